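"""GCTA binary GRM triple: <prefix>.grm.bin / .grm.N.bin / .grm.id.

The bin file is the lower triangle (diagonal included) of the symmetric
matrix as little-endian float32, pair order (0,0), (1,0), (1,1), (2,0), ...;
the N file holds the per-pair variant counts in the same order; the id file
is two tab-separated columns (family id, individual id).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_grm", "read_grm", "GRMFormatError"]


class GRMFormatError(ValueError):
    """Raised when a GRM triple is inconsistent."""


def _tril_order(n: int):
    i, j = np.tril_indices(n)
    return i, j


def write_grm(prefix: str, K: np.ndarray, ids=None,
              n_variants: int | np.ndarray = 0) -> None:
    K = np.asarray(K)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("GRM must be square")
    n = K.shape[0]
    ids = [f"I{k}" for k in range(n)] if ids is None else list(map(str, ids))
    if len(ids) != n:
        raise ValueError("id count does not match matrix size")
    i, j = _tril_order(n)
    K[i, j].astype("<f4").tofile(f"{prefix}.grm.bin")
    counts = np.broadcast_to(np.asarray(n_variants, dtype="<f4"), i.shape)
    np.ascontiguousarray(counts, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm(prefix: str):
    """Returns (K, ids, n_variants) from a GCTA binary triple."""
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)["iid"].tolist()
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    want = n * (n + 1) // 2
    if vals.size != want:
        raise GRMFormatError(
            f"{prefix}.grm.bin holds {vals.size} values but the id file "
            f"implies {want}")
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if counts.size not in (want, 0):
        raise GRMFormatError(f"{prefix}.grm.N.bin has wrong length")
    K = np.zeros((n, n))
    i, j = _tril_order(n)
    K[i, j] = vals
    K[j, i] = vals
    return K, ids, counts
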