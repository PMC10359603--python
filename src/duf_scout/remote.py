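"""Best-effort retrieval of deposited PDB entries, with local caching.

Network access is optional for everything in this package except the two
deposited-ensemble statistics; when no mirror is reachable the caller gets
``None`` (or an exception from :func:`fetch_pdb` with ``required=True``)
and should degrade gracefully.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
from pathlib import Path
from typing import Optional

PDB_MIRRORS = (
    "https://files.rcsb.org/download/{code}.pdb",
    "https://www.ebi.ac.uk/pdbe/entry-files/download/pdb{code_lower}.ent",
)

ENV_OVERRIDE = "DUF_SCOUT_PDB_DIR"


def fetch_pdb(code: str, cache_dir="scratch", timeout: float = 30.0,
              required: bool = False) -> Optional[Path]:
    """Return a local path to ``<code>.pdb``, downloading it if necessary.

    Looks, in order, at ``$DUF_SCOUT_PDB_DIR/<code>.pdb``, the cache
    directory, then the public mirrors.  Returns None (or raises when
    ``required``) if the entry cannot be obtained.
    """
    code = code.upper()
    override = os.environ.get(ENV_OVERRIDE)
    if override:
        candidate = Path(override) / f"{code}.pdb"
        if candidate.exists():
            return candidate
    cache = Path(cache_dir)
    cached = cache / f"{code}.pdb"
    if cached.exists():
        return cached
    cache.mkdir(parents=True, exist_ok=True)
    last_error: Optional[Exception] = None
    for template in PDB_MIRRORS:
        url = template.format(code=code, code_lower=code.lower())
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
            if b"ATOM" not in data[:100000]:
                raise ValueError(f"unexpected payload from {url}")
            cached.write_bytes(data)
            return cached
        except (urllib.error.URLError, OSError, ValueError) as exc:
            last_error = exc
    if required:
        raise RuntimeError(
            f"PDB entry {code} is not available offline and no mirror was "
            f"reachable (last error: {last_error}); set ${ENV_OVERRIDE} to a "
            f"directory containing {code}.pdb to run this computation")
    return None
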