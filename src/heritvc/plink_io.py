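"""PLINK bed/bim/fam reading and writing, plus panel (de)serialisation.

Genotypes are stored SNP-major in the standard 2-bit encoding.  We adopt
the convention that allele A1 is the alternate allele, so the stored codes
map to alternate-allele counts: 0b00 -> 2, 0b10 -> 1, 0b11 -> 0 (0b01 is
missing, unsupported on write).  Round trips are lossless for {0, 1, 2}
matrices and the fam file carries parent links, so a pedigree and sibship
matrix can be reconstructed from a written triple.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import GeneticMap, HaplotypePool, Pedigree

__all__ = [
    "write_plink",
    "read_plink",
    "fam_to_pedigree",
    "save_panel",
    "load_panel",
    "PlinkFormatError",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triple is malformed."""


def write_plink(prefix: str, genotypes: np.ndarray, positions: np.ndarray,
                chrom: np.ndarray | None = None,
                ids: np.ndarray | None = None,
                father: np.ndarray | None = None,
                mother: np.ndarray | None = None,
                sex: np.ndarray | None = None,
                snp_ids: np.ndarray | None = None) -> None:
    """Write a genotype matrix (individuals x sites, values in {0,1,2})."""
    G = np.asarray(genotypes)
    if G.ndim != 2:
        raise ValueError("genotypes must be 2-D")
    if G.size and (G.min() < 0 or G.max() > 2):
        raise ValueError("genotypes must be in {0, 1, 2}")
    n, m = G.shape
    positions = np.asarray(positions)
    if positions.size != m:
        raise ValueError("positions length does not match site count")
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom) + 1
    ids = np.array([f"I{k}" for k in range(n)]) if ids is None else \
        np.asarray(ids).astype(str)

    # fam: FID IID father mother sex phenotype
    fam = pd.DataFrame({
        "fid": ids, "iid": ids,
        "father": father if father is not None else ["0"] * n,
        "mother": mother if mother is not None else ["0"] * n,
        "sex": sex if sex is not None else [0] * n,
        "pheno": [-9] * n,
    })
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    bim = pd.DataFrame({
        "chrom": chrom,
        "snp": snp_ids if snp_ids is not None
        else [f"snp{c}_{p}" for c, p in zip(chrom, positions)],
        "cm": 0.0,
        "pos": positions,
        "a1": "A",        # alternate
        "a2": "G",        # reference
    })
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    # SNP-major 2-bit codes, LSB-first within each byte
    codes = np.where(G == 2, 0, np.where(G == 1, 2, 3)).astype(np.uint8)
    nb = (n + 3) // 4
    padded = np.zeros((m, 4 * nb), dtype=np.uint8)
    padded[:, :n] = codes.T
    shaped = padded.reshape(m, nb, 4)
    weights = np.array([1, 4, 16, 64], dtype=np.uint8)
    packed = (shaped * weights).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str):
    """Read a bed/bim/fam triple; returns (genotypes, bim, fam) with the
    genotype matrix holding alternate-allele counts (A1 counts)."""
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex",
                             "pheno"], dtype=str)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"])
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise PlinkFormatError(
                f"{prefix}.bed: bad magic bytes {magic!r} (expected "
                "SNP-major PLINK bed)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    nb = (n + 3) // 4
    if data.size != m * nb:
        raise PlinkFormatError(
            f"{prefix}.bed: {data.size} data bytes but fam/bim imply "
            f"{m} x {nb}")
    mat = data.reshape(m, nb)
    G = np.empty((n, m), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        codes = (mat[:, cols // 4] >> (2 * k)) & 3
        if np.any(codes == 1):
            raise PlinkFormatError(f"{prefix}.bed: missing genotypes are "
                                   "not supported")
        G[cols] = np.select([codes == 0, codes == 2, codes == 3],
                            [2, 1, 0]).T
    return G, bim, fam


def fam_to_pedigree(fam: pd.DataFrame) -> Pedigree:
    """Build a pedigree from fam parent links.

    Parents referenced but absent from the sample are added as ungenotyped
    founders (so every linked individual has either both parents present or
    none).
    """
    ids = fam["iid"].astype(str).tolist()
    known = set(ids)
    extra = []
    for col in ("father", "mother"):
        for v in fam[col].astype(str):
            if v not in ("0", "", "nan") and v not in known:
                known.add(v)
                extra.append(v)
    all_ids = np.array(extra + ids)
    lookup = {v: k for k, v in enumerate(all_ids.tolist())}
    n = all_ids.size
    father = np.full(n, -1, dtype=np.int64)
    mother = np.full(n, -1, dtype=np.int64)
    sex = np.zeros(n, dtype=np.int8)
    genotyped = np.zeros(n, dtype=bool)
    off = len(extra)
    for r, iid in enumerate(ids):
        k = lookup[iid]
        genotyped[k] = True
        f = str(fam["father"].iloc[r])
        m = str(fam["mother"].iloc[r])
        if f not in ("0", "", "nan"):
            father[k] = lookup[f]
            mother[k] = lookup[m]
        sex[k] = int(float(fam["sex"].iloc[r] or 0))
    return Pedigree(all_ids, father, mother, sex, genotyped)


# ---------------------------------------------------------------------------
# Reference panels (runtime artifacts; npz container)
# ---------------------------------------------------------------------------

def save_panel(path: str, pools: list[HaplotypePool]) -> None:
    arrays = {"n_chrom": np.array([len(pools)])}
    for c, p in enumerate(pools):
        arrays[f"alleles_{c}"] = p.alleles
        arrays[f"positions_{c}"] = p.positions
        arrays[f"cm_{c}"] = p.gmap.cm
    np.savez_compressed(path, **arrays)


def load_panel(path: str) -> list[HaplotypePool]:
    with np.load(path) as z:
        n = int(z["n_chrom"][0])
        return [HaplotypePool(z[f"alleles_{c}"],
                              GeneticMap(z[f"positions_{c}"], z[f"cm_{c}"]))
                for c in range(n)]
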