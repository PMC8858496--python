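"""On-disk formats: PLINK 1 bed/bim/fam and tab-separated alternatives.

The PLINK 1 binary codec is implemented here directly (SNP-major, two
bits per genotype: 00=hom alt-count-2 ... following the convention that
stored codes 0b00/0b10/0b11 mean 2/1/0 copies of allele1 and 0b01 means
missing).  We write dosages as counts of the alt allele (bim allele1 =
alt), so a round trip preserves the dosage matrix exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from heatgp.errors import DataError
from heatgp.simdata import GenotypeMatrix, validate_snp_map

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# stored 2-bit code -> alt-allele dosage (allele1 = alt); 0b01 = missing
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam for a genotype matrix (no missing genotypes)."""
    prefix = str(prefix)
    n, m = genotypes.dosages.shape
    dos = genotypes.dosages.astype(np.int8)
    if ((dos < 0) | (dos > 2)).any():
        raise DataError("dosages outside {0,1,2} cannot be written to bed")

    codes = np.empty((m, n), dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[dos.T == d] = c
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    packed[:, :n] = codes
    packed = (packed[:, 0::4] | (packed[:, 1::4] << 2)
              | (packed[:, 2::4] << 4) | (packed[:, 3::4] << 6))
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())

    smap = genotypes.snp_map
    bim = pd.DataFrame({
        "chrom": smap["chromosome"], "snp_id": smap["snp_id"], "cm": 0.0,
        "pos": smap["position_bp"], "a1": smap["alt_allele"], "a2": smap["ref_allele"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": genotypes.breed, "iid": genotypes.individual_ids,
        "father": 0, "mother": 0, "sex": 0, "phen": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(prefix: str | Path, tier_map: dict | None = None) -> GenotypeMatrix:
    """Read bed/bim/fam back into a GenotypeMatrix.

    ``tier_map`` optionally assigns array/sequence tiers by snp_id
    (default: every SNP is labelled 'sequence').
    """
    prefix = str(prefix)
    bim = pd.read_csv(prefix + ".bim", sep="\t", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix + ".fam", sep="\t", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "phen"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise DataError(f"{prefix}.bed is not a SNP-major PLINK 1 bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise DataError("bed payload size does not match bim/fam dimensions")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dos = _CODE_TO_DOSAGE[codes[:, :n]].T
    if (dos < 0).any():
        raise DataError("missing genotypes are not supported")

    tiers = [tier_map.get(s, "sequence") if tier_map else "sequence"
             for s in bim["snp_id"]]
    snp_map = pd.DataFrame({
        "snp_id": bim["snp_id"], "chromosome": bim["chrom"],
        "position_bp": bim["pos"], "ref_allele": bim["a2"],
        "alt_allele": bim["a1"], "tier": tiers,
    })
    validate_snp_map(snp_map)
    return GenotypeMatrix(dos, snp_map, fam["iid"].to_numpy(dtype=object),
                          fam["fid"].to_numpy(dtype=object))


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path,
                     map_path: str | Path | None = None) -> None:
    """Tab-separated dosage matrix (individuals x SNPs) plus SNP map."""
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_ids)
    df.insert(0, "individual_id", genotypes.individual_ids)
    df.insert(1, "breed", genotypes.breed)
    df.to_csv(path, sep="\t", index=False)
    if map_path:
        genotypes.snp_map.to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    snp_map = pd.read_csv(map_path, sep="\t")
    validate_snp_map(snp_map)
    ids = df["individual_id"].to_numpy(dtype=object)
    breed = df["breed"].to_numpy(dtype=object)
    dos = df.drop(columns=["individual_id", "breed"]).to_numpy(dtype=np.int8)
    if list(df.columns[2:]) != list(snp_map["snp_id"]):
        raise DataError("dosage columns and SNP map disagree")
    return GenotypeMatrix(dos, snp_map, ids, breed)
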