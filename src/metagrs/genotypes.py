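"""Genotype dosage matrices and PLINK/VCF I/O.

Dosages count copies of the declared effect allele (the PLINK A1 /
VCF ALT allele) and live in ``[0, 2]``; missing calls are ``NaN``.
The PLINK bed reader/writer implements the SNP-major 2-bit layout of
the bed/bim/fam trio directly; VCF is read through cyvcf2 (``GT`` hard
calls or the ``DS`` dosage field when present).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> effect (A1) allele dosage
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """An ``n_samples x n_variants`` dosage matrix with variant metadata.

    ``variants`` has columns ``chrom, pos, id, ea, oa``; ``dosages[i, j]``
    is sample *i*'s count of variant *j*'s effect allele.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        d = self.dosages
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2] or be missing (NaN)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def all_missing_variants(self) -> np.ndarray:
        """Boolean mask of variants with no observed calls."""
        return np.all(np.isnan(self.dosages), axis=0)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam trio; the effect allele is stored as A1."""
    prefix = Path(prefix)
    fam = pd.DataFrame(
        {
            "fid": gm.sample_ids,
            "iid": gm.sample_ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": gm.variants["chrom"],
            "id": gm.variants["id"],
            "cm": 0,
            "pos": gm.variants["pos"],
            "a1": gm.variants["ea"],
            "a2": gm.variants["oa"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n = gm.n_samples
    # dosage -> 2-bit code: 2->00, missing->01, 1->10, 0->11
    code = np.full(gm.dosages.shape, 1, dtype=np.uint8)  # missing
    code[gm.dosages == 2] = 0
    code[gm.dosages == 1] = 2
    code[gm.dosages == 0] = 3
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(gm.n_variants):
            col = code[:, j]
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for k in range(4):
                chunk = col[k::4]
                packed[: len(chunk)] |= chunk << (2 * k)
            fh.write(packed.tobytes())


def _read_plink(prefix: Path) -> GenotypeMatrix:
    fam_path, bim_path, bed_path = (prefix.with_suffix(s) for s in (".fam", ".bim", ".bed"))
    for p in (fam_path, bim_path, bed_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file {p}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise FormatError(f"{bim_path}: expected 6 columns, got {bim.shape[1]}")
    sample_ids = fam[1].tolist()
    variants = pd.DataFrame(
        {
            "chrom": bim[0].astype(str),
            "pos": pd.to_numeric(bim[3]).astype(np.int64),
            "id": bim[1].astype(str),
            "ea": bim[4].astype(str),
            "oa": bim[5].astype(str),
        }
    )
    n, m = len(sample_ids), len(variants)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not SNP-major bed)")
    body = raw[3:]
    if body.size != n_bytes * m:
        raise FormatError(
            f"{bed_path}: truncated or inconsistent ({body.size} bytes, expected {n_bytes * m})"
        )
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return GenotypeMatrix(sample_ids, variants, dosages)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCF (GT field).

    The effect allele is written as ALT so that ALT-dosage orientation
    matches the in-memory convention.
    """
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(gm.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_variants):
            v = gm.variants.iloc[j]
            calls = [
                gt_of.get(d, "./.") if np.isfinite(d) else "./."
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['oa']}\t{v['ea']}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"{path}: only biallelic records supported ({var.ID})")
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "id": var.ID if var.ID else f"{var.CHROM}:{var.POS}",
                "ea": var.ALT[0],
                "oa": var.REF,
            }
        )
        ds = var.format("DS") if "DS" in (var.FORMAT or []) else None
        if ds is not None:
            col = ds.astype(float).ravel()
        else:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            lut = np.array([0.0, 1.0, np.nan, 2.0])
            col = lut[var.gt_types]
        cols.append(col)
    if not cols:
        raise FormatError(f"{path}: no variant records")
    dosages = np.column_stack(cols)
    if dosages.shape[0] != len(sample_ids):
        raise FormatError(f"{path}: sample/variant dimension mismatch")
    return GenotypeMatrix(sample_ids, pd.DataFrame(rows), dosages)


def read_genotypes(path: str | Path, format: str = "bed-bim-fam") -> GenotypeMatrix:
    """Read a genotype panel.

    ``format`` is ``"bed-bim-fam"`` (``path`` is the trio prefix) or
    ``"vcf"``.  Dosages count the declared effect allele (A1 / ALT);
    missing calls are preserved as NaN.
    """
    path = Path(path)
    if format == "bed-bim-fam":
        return _read_plink(path.with_suffix("") if path.suffix == ".bed" else path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValidationError(f"unknown genotype format {format!r}")
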