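import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_orfs, random_dna, rc
from duf_scout.prf_reconstruct import (
    FusionError, NucleotideLocus, detect_prf, find_orfs, fuse,
    reconstruct_locus,
)
from duf_scout.synthetic_data import SimLocusSpec, gen_loci


def fsea_set(seed=1, n=5, **kw):
    loci, _, truth = gen_loci(SimLocusSpec(seed=seed, n_fsea_like=n, **kw))
    return loci, truth.by_id()


class TestFindOrfs:
    def test_hand_translatable(self):
        locus = NucleotideLocus(id="x", sequence="ATGAAATAA")
        orfs = find_orfs(locus, 1)
        assert len(orfs) == 1
        assert orfs[0].translation == "MK"
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (0, 9, "+")

    def test_strand_symmetry(self):
        locus = NucleotideLocus(id="x", sequence="ATGAAATAA")
        rev = NucleotideLocus(id="x", sequence=rc(locus.sequence))
        orfs = find_orfs(rev, 1)
        assert len(orfs) == 1
        assert orfs[0].translation == "MK"
        assert orfs[0].strand == "-"
        assert (orfs[0].start, orfs[0].end) == (0, 9)

    def test_brute_force_oracle_10kb(self, rng):
        seq = random_dna(rng, 10_000)
        locus = NucleotideLocus(id="big", sequence=seq)
        got = {(o.start, o.end, o.strand, o.translation)
               for o in find_orfs(locus, 50)}
        assert got == brute_force_orfs(seq, 50)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 1500)
        locus = NucleotideLocus(id=f"s{seed}", sequence=seq)
        got = {(o.start, o.end, o.strand, o.translation)
               for o in find_orfs(locus, 10)}
        assert got == brute_force_orfs(seq, 10)

    def test_n_dense_warns_not_fails(self):
        locus = NucleotideLocus(id="n", sequence="N" * 200 + "ATGAAATAA")
        orfs = find_orfs(locus, 1)
        assert orfs and all(o.n_warning for o in orfs)

    def test_startless_option(self):
        # no ATG before the stop: invisible by default, visible start-less
        locus = NucleotideLocus(id="x", sequence="AAACCCGGGTAA")
        assert find_orfs(locus, 1) == []
        orfs = [o for o in find_orfs(locus, 1, include_startless=True)
                if o.strand == "+"]
        assert any(not o.has_start and o.translation == "KPG" for o in orfs)

    def test_min_len_validation(self):
        locus = NucleotideLocus(id="x", sequence="ATGAAATAA")
        with pytest.raises(ValueError):
            find_orfs(locus, 0)


class TestDetectPrf:
    def test_truth_coordinate(self):
        loci, tmap = fsea_set(seed=3)
        for locus in loci:
            t = tmap[locus.id]
            calls = [c for c in detect_prf(locus, find_orfs(locus, 30))
                     if c.strand == "+"]
            assert len(calls) == 1
            assert calls[0].motif_start == t.prf_motif_start
            assert calls[0].motif_seq == "TGGGGG"
            assert calls[0].motif_mismatches == 0
            assert calls[0].overlap_nt >= 1

    def test_single_orf_locus_empty(self):
        loci, _, _ = gen_loci(SimLocusSpec(seed=4, n_fsea_like=0, n_qsem_like=3))
        for locus in loci:
            assert detect_prf(locus, find_orfs(locus, 10)) == []

    def test_mismatch_tolerance(self):
        loci, tmap = fsea_set(seed=5, n=1)
        locus = loci[0]
        t = tmap[locus.id]
        m = t.prf_motif_start
        mutated = locus.sequence[:m] + "A" + locus.sequence[m + 1 :]
        lmut = NucleotideLocus(id=locus.id, sequence=mutated)
        orfs = find_orfs(lmut, 30)
        at_truth = lambda calls: [c for c in calls
                                  if c.strand == "+" and c.motif_start == m]
        assert at_truth(detect_prf(lmut, orfs, max_mismatch=0)) == []
        calls = at_truth(detect_prf(lmut, orfs, max_mismatch=1))
        assert len(calls) == 1 and calls[0].motif_mismatches == 1
        assert calls[0].motif_seq == "AGGGGG"

    def test_sorted_by_mismatch_then_position(self):
        loci, _ = fsea_set(seed=6, n=3)
        for locus in loci:
            calls = detect_prf(locus, find_orfs(locus, 30), max_mismatch=1)
            keys = [(c.motif_mismatches, c.motif_start) for c in calls]
            assert keys == sorted(keys)


class TestFuse:
    def test_truth_fusion_exact(self):
        loci, tmap = fsea_set(seed=7)
        for locus in loci:
            t = tmap[locus.id]
            call = [c for c in detect_prf(locus, find_orfs(locus, 30))
                    if c.strand == "+"][0]
            rec = fuse(locus, call)
            assert rec.sequence == t.protein
            assert rec.provenance == "PRF_FUSED"
            assert rec.junction_residue == t.junction_residue

    def test_junction_reads_wg(self):
        # TGG GGG read through the +1 edit puts W,G at the junction
        loci, _ = fsea_set(seed=8, n=3)
        for locus in loci:
            rec, = [fuse(locus, c) for c in detect_prf(locus, find_orfs(locus, 30))
                    if c.strand == "+"]
            j = rec.junction_residue
            assert rec.sequence[j - 2 : j] == "WG"

    def test_null_call_identity(self):
        loci, gff, truth = gen_loci(SimLocusSpec(seed=9, n_fsea_like=0,
                                                 n_qsem_like=1))
        locus = loci[0]
        cds = [r for r in gff if r[2] == "CDS"][0]
        start, end = cds[3] - 1, cds[4]  # GFF3 is 1-based inclusive
        orf = [o for o in find_orfs(locus, 30)
               if o.strand == "+" and (o.start, o.end) == (start, end)][0]
        rec = fuse(locus, orf=orf)
        assert rec.provenance == "SINGLE_ORF"
        assert rec.junction_residue is None
        assert rec.sequence == truth.genes[0].protein

    def test_internal_stop_raises_fusion_error(self):
        loci, tmap = fsea_set(seed=10, n=1)
        locus = loci[0]
        t = tmap[locus.id]
        # plant a +1-frame stop downstream of the junction
        pos = t.prf_motif_start + 6 + 1 + 9  # on a +1 codon boundary
        seq = locus.sequence[: pos] + "TAA" + locus.sequence[pos + 3 :]
        broken = NucleotideLocus(id="broken", sequence=seq)
        orfs = find_orfs(locus, 30)  # original annotation, stale for broken
        calls = [c for c in detect_prf(locus, orfs) if c.strand == "+"]
        with pytest.raises(FusionError) as exc:
            fuse(broken, calls[0])
        assert exc.value.stop_position == pos

    def test_fusion_length_arithmetic(self):
        loci, tmap = fsea_set(seed=12, n=10)
        for locus in loci:
            t = tmap[locus.id]
            m_end = t.prf_motif_start + 6
            up_codons = (m_end - t.orf1[0]) // 3
            down_codons = (t.orf2[1] - 3 - (m_end + 1)) // 3
            assert len(t.protein) == up_codons + down_codons


class TestProperties:
    def test_strand_invariance(self):
        loci, _ = fsea_set(seed=13, n=5)
        for locus in loci:
            fwd, _ = reconstruct_locus(locus)
            rev, _ = reconstruct_locus(
                NucleotideLocus(id=locus.id, sequence=rc(locus.sequence)))
            assert sorted(p.sequence for p in fwd) == sorted(
                p.sequence for p in rev)

    def test_roundtrip_recovers_all_fusions(self):
        loci, tmap = fsea_set(seed=14, n=20)
        for locus in loci:
            proteins, _ = reconstruct_locus(locus)
            assert tmap[locus.id].protein in [p.sequence for p in proteins]

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_any_seed(self, seed):
        loci, _, truth = gen_loci(SimLocusSpec(seed=seed, n_fsea_like=1))
        proteins, _ = reconstruct_locus(loci[0])
        assert truth.genes[0].protein in [p.sequence for p in proteins]
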