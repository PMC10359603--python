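import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_ir, brute_force_redundancy, random_dna, rc
from duf_scout.irbox_scan import (
    IRBox, naive_profile, redundancy_filter, scan, split_profile,
    profile_from_probs, write_meme_minimal,
)
from duf_scout.synthetic_data import gen_upstreams

ONE_HOT = profile_from_probs(np.eye(4)[[2, 3, 1, 2, 0, 1]])  # GTCGAC


def planted_window(spacer=16, seed=0):
    windows, truth = gen_upstreams(1, {spacer: 1.0}, ONE_HOT, seed=seed)
    return windows[0], truth[0]


class TestScan:
    def test_planted_perfect_ir_span_28(self):
        w, (_, h1, h2, spacer) = planted_window(spacer=16)
        boxes = scan(w, max_mismatch=0)
        mine = [b for b in boxes if b.hex1_start == h1 and b.spacer == 16]
        assert len(mine) == 1
        box = mine[0]
        assert box.mismatches == 0
        assert box.total_span == 28
        assert box.centre_distance == 22

    def test_homopolymer_no_hit(self):
        assert scan("A" * 60, max_mismatch=0) == []

    def test_brute_force_oracle_200_windows(self, rng):
        for _ in range(200):
            w = random_dna(rng, int(rng.integers(30, 70)))
            got = {(b.hex1_start, b.spacer, b.mismatches)
                   for b in scan(w, max_mismatch=2)}
            assert got == brute_force_ir(w, 6, (15, 16), 2)

    def test_short_window_raises(self):
        with pytest.raises(ValueError):
            scan("ACGT" * 6)  # 24 < 6+16+6

    def test_sorted_output(self, rng):
        w = random_dna(rng, 80)
        boxes = scan(w, max_mismatch=3)
        keys = [(b.mismatches, b.hex1_start, b.spacer) for b in boxes]
        assert keys == sorted(keys)

    def test_translation_equivariance(self, rng):
        w, _ = planted_window(seed=5)
        pad = "ACGTA"
        shifted = scan(pad + w, max_mismatch=1)
        base = scan(w, max_mismatch=1)
        base_keys = {(b.hex1_start + len(pad), b.spacer, b.mismatches)
                     for b in base}
        shifted_keys = {(b.hex1_start, b.spacer, b.mismatches)
                        for b in shifted}
        # every original hit appears shifted by the pad length
        assert base_keys <= shifted_keys

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            IRBox(window_id="w", hex1_start=0, hex2_start=10, spacer=16)


class TestRedundancyFilter:
    def test_identical_collapse(self):
        assert redundancy_filter(["ACGTACGT", "ACGTACGT"]) == ["ACGTACGT"]

    def test_below_threshold_all_kept(self):
        # 20-mers differing at 3 positions = 85% identity < 90%
        base = "ACGTACGTACGTACGTACGT"
        variant = "TCGTTCGTACGTACGTACGA"
        assert sum(a == b for a, b in zip(base, variant)) / 20 == 0.85
        assert redundancy_filter([base, variant], 0.90) == [base, variant]

    def test_brute_force_oracle(self, rng):
        # low-cardinality alphabet sampling gives plenty of near-duplicates
        pool = [random_dna(rng, 12) for _ in range(8)]
        windows = []
        for _ in range(100):
            w = list(pool[rng.integers(len(pool))])
            if rng.random() < 0.7:
                w[rng.integers(12)] = "ACGT"[rng.integers(4)]
            windows.append("".join(w))
        assert redundancy_filter(windows, 0.9) == brute_force_redundancy(
            windows, 0.9)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            redundancy_filter(["ACGT", "ACG"])


class TestSplitProfile:
    def test_identical_windows_full_information(self):
        w, (_, h1, h2, spacer) = planted_window()
        box = [b for b in scan(w, max_mismatch=0)
               if b.hex1_start == h1 and b.spacer == spacer][0]
        profile = split_profile([w] * 10, [box] * 10)
        assert profile.n_sequences == 10
        np.testing.assert_allclose(profile.information, 2.0)
        assert np.all(profile.counts.sum(axis=1) == 10)

    def test_central_conservation_entropy_oracle(self):
        # hexamer with invariant central two bases, uniform elsewhere
        probs = np.full((6, 4), 0.25)
        probs[2] = [0, 0, 1, 0]  # G
        probs[3] = [0, 0, 0, 1]  # T... revcomp partner central too
        pfm = profile_from_probs(probs)
        n = 500
        windows, truth = gen_upstreams(n, {16: 1.0}, pfm, seed=7)
        boxes = []
        for w, (_, h1, h2, sp) in zip(windows, truth):
            boxes.append(IRBox(window_id="", hex1_start=h1, hex2_start=h2,
                               spacer=sp))
        profile = split_profile(windows, boxes)
        labels = profile.labels
        info = dict(zip(labels, profile.information))
        for lab in ("hex1.3", "hex1.4", "hex2.3", "hex2.4"):
            assert info[lab] == pytest.approx(2.0, abs=0.05)
        for lab in ("hex1.1", "hex1.6", "hex2.1", "hex2.6"):
            assert info[lab] < 0.1

    def test_mixed_spacers_no_smearing(self):
        n = 400
        windows, truth = gen_upstreams(
            n, {15: 0.5, 16: 0.5}, ONE_HOT, seed=11, fixed_box_offset=10)
        boxes = [IRBox(window_id="", hex1_start=h1, hex2_start=h2, spacer=sp)
                 for (_, h1, h2, sp) in truth]
        anchored = split_profile(windows, boxes)
        hex2_info = [v for lab, v in zip(anchored.labels, anchored.information)
                     if lab.startswith("hex2")]
        assert min(hex2_info) == pytest.approx(2.0, abs=1e-9)
        # the naive fixed-coordinate stack smears hexamer 2 over two offsets
        naive = naive_profile(windows)
        smeared = naive.information[10 + 6 + 16 : 10 + 6 + 16 + 6]
        assert max(smeared) < 1.8

    def test_missing_anchor_skipped(self):
        w, (_, h1, h2, sp) = planted_window()
        box = IRBox(window_id="", hex1_start=h1, hex2_start=h2, spacer=sp)
        profile = split_profile([w, w], [box, None])
        assert profile.n_sequences == 1 and profile.skipped == 1

    def test_revcomp_mirror_image(self):
        windows, truth = gen_upstreams(100, {16: 1.0}, ONE_HOT, seed=13)
        boxes = [IRBox(window_id="", hex1_start=h1, hex2_start=h2, spacer=sp)
                 for (_, h1, h2, sp) in truth]
        fwd = split_profile(windows, boxes)
        rc_windows = [rc(w) for w in windows]
        L = len(windows[0])
        rc_boxes = [IRBox(window_id="", hex1_start=L - (b.hex2_start + 6),
                          hex2_start=L - (b.hex1_start + 6), spacer=b.spacer)
                    for b in boxes]
        rev = split_profile(rc_windows, rc_boxes)
        # hexamer-1 columns of the mirror equal complemented, reversed
        # hexamer-2 columns of the original (A<->T, C<->G = reversed row order)
        f = {lab: row for lab, row in zip(fwd.labels, fwd.counts)}
        r = {lab: row for lab, row in zip(rev.labels, rev.counts)}
        for i in range(6):
            np.testing.assert_allclose(
                r[f"hex2.{i + 1}"], f[f"hex1.{6 - i}"][::-1])
            np.testing.assert_allclose(
                r[f"hex1.{i + 1}"][::-1], f[f"hex2.{6 - i}"])

    def test_meme_output(self, tmp_path):
        w, (_, h1, h2, sp) = planted_window()
        box = IRBox(window_id="", hex1_start=h1, hex2_start=h2, spacer=sp)
        profile = split_profile([w], [box])
        out = tmp_path / "pfm.meme"
        write_meme_minimal(profile, "box", out)
        text = out.read_text()
        assert "MEME version 4" in text and "letter-probability matrix" in text


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31))
def test_scan_counts_property(seed):
    rng = np.random.default_rng(seed)
    w = random_dna(rng, 40)
    boxes = scan(w, max_mismatch=6)  # every placement qualifies
    expected = sum(max(0, len(w) - (12 + s) + 1) for s in (15, 16))
    assert len(boxes) == expected
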