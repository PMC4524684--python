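"""Thin convenience helper for fetching PDB entries.

Network access is deliberately minimal: one function, explicit timeout,
local caching.  Everything else in the package works from local files.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

__all__ = ["fetch_pdb"]

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_pdb(pdb_id: str, cache_dir: str | Path = ".",
              timeout: float = 15.0) -> Path:
    """Download a PDB entry (or reuse a cached copy) and return its path.

    Raises ``OSError`` if the file is not cached and the download fails
    (e.g. no network access).
    """
    pdb_id = pdb_id.upper()
    if len(pdb_id) != 4:
        raise ValueError(f"{pdb_id!r} is not a PDB accession")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = _RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as response:
            data = response.read()
    except Exception as exc:
        raise OSError(f"cannot fetch {pdb_id} from {url}: {exc}") from exc
    dest.write_bytes(data)
    return dest
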