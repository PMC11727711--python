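"""VCF input/output and the resequencing SNP filters.

Genotypes are held as a samples x variants int8 matrix counting alternate
alleles (0/1/2), with -1 for a missing call; the variant table is a pandas
DataFrame sorted by (chrom, pos).  Reading goes through cyvcf2; writing
emits minimal VCF v4.2 with GT-only genotype fields.

Filters follow the resequencing pipeline exactly as stated: keep variants
with minor allele frequency > 0.05, per-variant missing fraction < 0.7, and
exactly two alleles — strict inequalities, applied in the order
biallelic -> missingness -> MAF, with per-rule removal counts reported.
Indels are parsed and retained in the table (the causative screen needs to
exclude them explicitly) but carry ``vtype == "indel"`` so association input
can drop them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariantDataset",
    "FilterConfig",
    "FilterReport",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "compute_maf",
    "missing_fraction",
    "apply_filters",
]

#: Genotype code for a missing diploid call.
MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


@dataclass
class VariantDataset:
    """Variant table + genotype matrix + sample names, kept aligned."""

    variants: pd.DataFrame  # columns: chrom, pos, id, ref, alt, vtype[, n_alleles]
    genotypes: np.ndarray   # (n_samples, n_variants) int8; -1 missing
    samples: list[str]

    def __post_init__(self) -> None:
        n_s, n_v = self.genotypes.shape
        if n_v != len(self.variants) or n_s != len(self.samples):
            raise ValueError("genotype matrix does not match variants/samples")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take(self, mask: np.ndarray) -> "VariantDataset":
        return VariantDataset(
            variants=self.variants.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, np.asarray(mask)],
            samples=list(self.samples),
        )

    def snps_only(self) -> "VariantDataset":
        return self.take((self.variants["vtype"] == "SNP").to_numpy())


@dataclass(frozen=True)
class FilterConfig:
    """Resequencing SNP filter thresholds (strict inequalities)."""

    maf_min: float = 0.05
    missing_max: float = 0.7
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 1 and 0 <= self.missing_max <= 1):
            raise ValueError("filter thresholds must lie in [0, 1]")


@dataclass
class FilterReport:
    removed: dict[str, int] = field(default_factory=dict)  # rule -> count, in order
    n_in: int = 0
    n_out: int = 0


def read_vcf(path: str | Path) -> VariantDataset:
    """Read a VCF (v4.x, plain or bgzipped) into a VariantDataset.

    Accepts phased and unphased diploid GT; ``./.`` becomes the missing
    code.  Multiallelic records are kept and flagged via ``n_alleles`` (the
    biallelic filter removes them); their genotype entry counts non-reference
    alleles.
    """
    import cyvcf2

    try:
        reader = cyvcf2.VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(reader.samples)
    rows, cols = [], []
    try:
        for rec_no, v in enumerate(reader, start=1):
            alts = v.ALT or []
            alt = alts[0] if alts else "."
            vtype = "SNP" if len(v.REF) == 1 and all(len(a) == 1 for a in alts) else "indel"
            rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, alt, vtype, 1 + len(alts)))
            g = np.array([a[:2] for a in v.genotypes], dtype=np.int16)
            col = np.where((g < 0).any(axis=1), MISSING, np.clip(g, 0, 1).sum(axis=1))
            cols.append(col.astype(np.int8))
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path} near record {len(rows) + 1}: {exc}") from exc
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "vtype", "n_alleles"])
    genotypes = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), np.int8)
    return VariantDataset(variants=variants, genotypes=genotypes, samples=samples)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(dataset: VariantDataset, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only sample columns."""
    path = Path(path)
    contigs = dict.fromkeys(dataset.variants["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=plumagemap\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.samples) + "\n")
        vt = dataset.variants
        for j in range(len(vt)):
            row = vt.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in dataset.genotypes[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row.get('id', '.')}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def compute_maf(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant minor allele frequency over non-missing alleles.

    Accepts a 1-D vector (one variant) or a samples x variants matrix and
    returns folded frequencies min(p, 1-p); NaN where every call is missing.
    """
    arr = np.asarray(genotypes)
    g = arr.reshape(-1, 1) if arr.ndim == 1 else arr
    present = g != MISSING
    n_alleles = 2 * present.sum(axis=0)
    alt = np.where(present, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    maf = np.minimum(p, 1 - p)
    return maf if arr.ndim > 1 else float(maf[0])


def missing_fraction(genotypes: np.ndarray) -> np.ndarray:
    g = np.atleast_2d(np.asarray(genotypes))
    return (g == MISSING).mean(axis=0)


def apply_filters(
    dataset: VariantDataset, config: FilterConfig | None = None
) -> tuple[VariantDataset, FilterReport]:
    """Apply the SNP filters in order biallelic -> missingness -> MAF.

    Variant order is preserved; a FilterReport carries per-rule removal
    counts (each rule counted among the survivors of the previous rule, so
    the counts sum to input minus output).  Applying the filters twice gives
    the same result as once.
    """
    config = config or FilterConfig()
    report = FilterReport(n_in=dataset.n_variants)
    keep = np.ones(dataset.n_variants, dtype=bool)

    if config.biallelic_only:
        if "n_alleles" in dataset.variants:
            bi = (dataset.variants["n_alleles"] == 2).to_numpy()
        else:
            bi = np.ones(dataset.n_variants, dtype=bool)
        report.removed["biallelic"] = int((keep & ~bi).sum())
        keep &= bi

    miss = missing_fraction(dataset.genotypes)
    ok_miss = miss < config.missing_max
    report.removed["missing"] = int((keep & ~ok_miss).sum())
    keep &= ok_miss

    maf = compute_maf(dataset.genotypes)
    ok_maf = np.nan_to_num(maf, nan=-1.0) > config.maf_min
    report.removed["maf"] = int((keep & ~ok_maf).sum())
    keep &= ok_maf

    report.n_out = int(keep.sum())
    return dataset.take(keep), report
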