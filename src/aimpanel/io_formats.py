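"""Genotype dataset containers and text-format I/O.

Supported formats
-----------------
- PLINK ``.ped``/``.map`` text dialect (one row per sample; two allele
  columns per SNP; missing genotype ``0 0``).
- VCF 4.x, biallelic SNP records only (read via :mod:`cyvcf2`; written as
  plain text with ``GT``-only genotype fields).
- EIGENSTRAT-style ``.geno``/``.snp``/``.ind`` triple (one digit per sample
  per SNP row; ``9`` missing).

Genotypes are stored internally as an ``int8`` dosage matrix counting copies
of ``allele_alt`` (0/1/2), with ``-1`` as the missing sentinel.  The PLINK
text dialect carries no ref/alt designation, so the PED reader orients each
SNP lexicographically (``allele_ref`` is the earlier base); writers for VCF
and EIGENSTRAT preserve the stored orientation exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: columns of the SNP metadata table, in storage order
SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "position_cm",
               "allele_ref", "allele_alt"]

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER["X"] = 23


class FormatError(ValueError):
    """A file does not conform to the expected text dialect."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


def chrom_sort_key(chrom: str) -> int:
    """Numeric ordering for chromosome labels 1-22, X."""
    try:
        return _CHROM_ORDER[str(chrom)]
    except KeyError:
        raise ValidationError(f"unsupported chromosome label: {chrom!r}")


@dataclass(frozen=True)
class SnpRecord:
    """A single biallelic SNP with physical and (optional) genetic position."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_ref: str
    allele_alt: str
    position_cm: float = np.nan

    def __post_init__(self):
        if self.allele_ref not in BASES or self.allele_alt not in BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be in {BASES}, got "
                f"{self.allele_ref}/{self.allele_alt}")
        if self.allele_ref == self.allele_alt:
            raise ValidationError(f"{self.snp_id}: ref and alt alleles equal")
        if self.position_bp < 0:
            raise ValidationError(f"{self.snp_id}: negative bp position")


@dataclass
class GenotypeDataset:
    """Samples x SNPs diploid dosage matrix with per-SNP metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    snps
        DataFrame with columns :data:`SNP_COLUMNS`, sorted by
        (chromosome, position_bp).
    calls
        ``int8`` array of shape (n_samples, n_snps); entries count copies of
        ``allele_alt`` (0/1/2) with -1 for missing.
    population_label
        Free-text label ("CEU", "YRI", "admixed", ...).
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    population_label: str = ""

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_samples, n_snps = len(self.samples), len(self.snps)
        if self.calls.shape != (n_samples, n_snps):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({n_samples} samples, {n_snps} snps)")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("calls contain entries outside {0,1,2,missing}")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValidationError(f"snps table missing columns {missing_cols}")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate snp_id values: {dupes}")
        order = self.snps.apply(
            lambda r: (chrom_sort_key(r["chromosome"]), r["position_bp"]), axis=1)
        if len(order) and not order.is_monotonic_increasing:
            raise ValidationError("snps not sorted by (chromosome, position_bp)")
        for col in ("allele_ref", "allele_alt"):
            if len(self.snps) and not self.snps[col].isin(BASES).all():
                raise ValidationError(f"invalid bases in {col}")
        if len(self.snps) and (self.snps["allele_ref"] == self.snps["allele_alt"]).any():
            raise ValidationError("ref == alt at some SNP")

    # -- conveniences --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if none)."""
        calls = self.calls.astype(float)
        calls[calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeDataset":
        """Restrict to the given SNPs (kept in this dataset's order)."""
        wanted = set(snp_ids)
        mask = self.snps["snp_id"].isin(wanted).to_numpy()
        return GenotypeDataset(
            samples=list(self.samples),
            snps=self.snps.loc[mask, SNP_COLUMNS],
            calls=self.calls[:, mask],
            population_label=self.population_label)

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeDataset":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return GenotypeDataset(
            samples=list(sample_ids),
            snps=self.snps.copy(),
            calls=self.calls[rows],
            population_label=self.population_label)

    def equals(self, other: "GenotypeDataset") -> bool:
        """Structural equality; cM positions compared to 1e-9 (formats that
        store Morgans reintroduce one float division on read)."""
        exact = [c for c in SNP_COLUMNS if c != "position_cm"]
        a = self.snps.reset_index(drop=True)
        b = other.snps.reset_index(drop=True)
        cm_a = a["position_cm"].to_numpy(float)
        cm_b = b["position_cm"].to_numpy(float)
        cm_close = len(cm_a) == len(cm_b) and bool(
            np.all((np.isnan(cm_a) & np.isnan(cm_b))
                   | (np.abs(cm_a - cm_b) <= 1e-9)))
        return (self.samples == other.samples
                and a[exact].equals(b[exact])
                and cm_close
                and np.array_equal(self.calls, other.calls))


def make_snp_table(records: Sequence[SnpRecord]) -> pd.DataFrame:
    """Build a sorted SNP metadata table from records."""
    df = pd.DataFrame(
        [{"snp_id": r.snp_id, "chromosome": str(r.chromosome),
          "position_bp": int(r.position_bp), "position_cm": r.position_cm,
          "allele_ref": r.allele_ref, "allele_alt": r.allele_alt}
         for r in records],
        columns=SNP_COLUMNS)
    key = df.apply(lambda r: (chrom_sort_key(r["chromosome"]),
                              r["position_bp"]), axis=1)
    return df.iloc[np.argsort(key, kind="stable")].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMapTable:
    """Per-chromosome anchor lists mapping physical (bp) to genetic (cM) position.

    Anchors must be strictly increasing in both coordinates within a
    chromosome; between anchors positions are interpolated linearly and
    outside the anchored range the nearest anchor's cM value is used.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, (bp, cm) in self.anchors.items():
            bp, cm = np.asarray(bp, float), np.asarray(cm, float)
            if len(bp) != len(cm) or len(bp) == 0:
                raise ValidationError(f"chromosome {chrom}: empty or ragged anchors")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValidationError(
                    f"chromosome {chrom}: anchors not strictly increasing")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMapTable":
        """Read a 3-column TSV (chrom, bp, cM), header optional."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = [c.lower() for c in df.columns]
        if not {"chrom", "bp"} <= set(cols):  # headerless file
            df = pd.read_csv(path, sep="\t", comment="#", header=None,
                             names=["chrom", "bp", "cm"], dtype=str)
        else:
            df.columns = cols
            df = df.rename(columns={"cm": "cm"})
        anchors = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.astype({"bp": float, "cm": float}).sort_values("bp")
            anchors[str(chrom)] = (grp["bp"].to_numpy(), grp["cm"].to_numpy())
        return cls(anchors)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for chrom in sorted(self.anchors, key=chrom_sort_key):
            bp, cm = self.anchors[chrom]
            rows.extend({"chrom": chrom, "bp": int(b), "cm": c}
                        for b, c in zip(bp, cm))
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def interpolate_cm(snps: pd.DataFrame, map_table: GeneticMapTable) -> pd.DataFrame:
    """Fill ``position_cm`` by piecewise-linear interpolation of map anchors.

    Positions outside the anchored range take the nearest anchor's cM value
    (constant extrapolation, as :func:`numpy.interp` does).
    """
    missing = sorted(set(snps["chromosome"].astype(str))
                     - set(map_table.anchors), key=chrom_sort_key)
    if missing:
        raise ValidationError(
            f"chromosomes absent from genetic map: {missing}")
    out = snps.copy()
    cm = np.empty(len(out))
    for chrom, grp in out.groupby("chromosome", sort=False):
        bp_anchor, cm_anchor = map_table.anchors[str(chrom)]
        cm[grp.index.to_numpy()] = np.interp(
            grp["position_bp"].to_numpy(float), bp_anchor, cm_anchor)
    out["position_cm"] = cm
    return out


def read_centromeres(path: str | Path) -> pd.DataFrame:
    """Read a BED file of centromere intervals -> (chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return df


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _ped_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in {".ped", ".map"} else p
    return stem.with_suffix(".ped"), stem.with_suffix(".map")


def _read_ped(path: str | Path, population_label: str) -> GenotypeDataset:
    ped_path, map_path = _ped_paths(path)
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chromosome", "snp_id", "position_cm",
                                "position_bp"],
                         dtype={"chromosome": str, "snp_id": str})
    n_snps = len(map_df)
    samples, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} "
                    f"fields, got {len(fields)}")
            samples.append(fields[1])
            rows.append(fields[6:])
    alleles = np.array(rows, dtype="U1").reshape(len(samples), n_snps, 2) \
        if rows else np.empty((0, n_snps, 2), dtype="U1")

    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    ref = np.empty(n_snps, dtype="U1")
    alt = np.empty(n_snps, dtype="U1")
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if any(a not in BASES for a in observed):
            raise FormatError(
                f"{ped_path}: non-ACGT allele {observed} at SNP "
                f"{map_df['snp_id'].iloc[j]}")
        if len(observed) > 2:
            raise FormatError(
                f"{ped_path}: >2 alleles at SNP {map_df['snp_id'].iloc[j]}")
        if len(observed) == 2:
            r, a = observed  # lexicographic orientation
        elif len(observed) == 1:
            # monomorphic: partner allele unknowable from PED; pick the first
            # base alphabetically that differs, then orient lexicographically
            other = next(b for b in BASES if b != observed[0])
            r, a = sorted((observed[0], other))
        else:  # fully missing column
            r, a = "A", "C"
        ref[j], alt[j] = r, a
        nonmiss = col[:, 0] != "0"
        calls[nonmiss, j] = (col[nonmiss] == alt[j]).sum(axis=1)

    snps = map_df.copy()
    snps["allele_ref"], snps["allele_alt"] = ref, alt
    snps["position_bp"] = snps["position_bp"].astype(int)
    snps["position_cm"] = snps["position_cm"].astype(float)
    snps = make_snp_table([
        SnpRecord(row.snp_id, row.chromosome, int(row.position_bp),
                  row.allele_ref, row.allele_alt, float(row.position_cm))
        for row in snps.itertuples()])
    # reorder calls to match sorted snp table
    col_index = {s: i for i, s in enumerate(map_df["snp_id"])}
    calls = calls[:, [col_index[s] for s in snps["snp_id"]]]
    return GenotypeDataset(samples, snps, calls, population_label)


def _write_ped(dataset: GenotypeDataset, path: str | Path) -> None:
    ped_path, map_path = _ped_paths(path)
    snps = dataset.snps
    with open(map_path, "w") as fh:
        for row in snps.itertuples():
            cm = 0.0 if pd.isna(row.position_cm) else row.position_cm
            fh.write(f"{row.chromosome}\t{row.snp_id}\t{cm!r}\t{row.position_bp}\n")
    ref = snps["allele_ref"].to_numpy()
    alt = snps["allele_alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(dataset.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, g in enumerate(dataset.calls[i]):
                if g == MISSING:
                    fields.extend(("0", "0"))
                elif g == 0:
                    fields.extend((ref[j], ref[j]))
                elif g == 1:
                    fields.extend((ref[j], alt[j]))
                else:
                    fields.extend((alt[j], alt[j]))
            fh.write(" ".join(fields) + "\n")
        if not dataset.samples:
            pass  # header-less empty file is valid PED


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _read_vcf(path: str | Path, population_label: str) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, dosage_cols = [], []
    n_skipped = 0
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1 \
                or variant.REF not in BASES or alts[0] not in BASES:
            n_skipped += 1
            continue
        chrom = str(variant.CHROM).removeprefix("chr")
        cm = variant.INFO.get("CM")
        records.append(SnpRecord(
            variant.ID or f"{chrom}:{variant.POS}", chrom, variant.POS,
            variant.REF, alts[0],
            float(cm) if cm is not None else np.nan))
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes or ()):
            a = gt[:-1]  # last entry is phasing flag
            if len(a) >= 2 and a[0] >= 0 and a[1] >= 0:
                col[i] = a[0] + a[1]
        dosage_cols.append(col)
    if n_skipped:
        logger.info("read_genotypes(vcf): skipped %d non-biallelic-SNP "
                    "records in %s", n_skipped, path)
    snps = make_snp_table(records)
    calls = (np.column_stack(dosage_cols) if dosage_cols
             else np.empty((len(samples), 0), dtype=np.int8))
    if len(records):
        col_index = {r.snp_id: i for i, r in enumerate(records)}
        calls = calls[:, [col_index[s] for s in snps["snp_id"]]]
    ds = GenotypeDataset(samples, snps, calls, population_label)
    ds.n_skipped = n_skipped
    return ds


def _write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    snps = dataset.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        # String, not Float: VCF Float INFO is parsed at 32-bit precision,
        # which would not round-trip the genetic map position
        fh.write('##INFO=<ID=CM,Number=1,Type=String,'
                 'Description="Genetic map position in cM">\n')
        for chrom in dict.fromkeys(snps["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if dataset.samples:
            header += "\tFORMAT\t" + "\t".join(dataset.samples)
        fh.write(header + "\n")
        for j, row in enumerate(snps.itertuples()):
            gts = "\t".join(_GT_CODE[int(g)] for g in dataset.calls[:, j])
            info = "." if pd.isna(row.position_cm) else f"CM={row.position_cm!r}"
            line = (f"{row.chromosome}\t{row.position_bp}\t{row.snp_id}\t"
                    f"{row.allele_ref}\t{row.allele_alt}\t.\t.\t{info}")
            if dataset.samples:
                line += "\tGT\t" + gts
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# EIGENSTRAT-style triple
# ---------------------------------------------------------------------------

def _eigen_paths(path: str | Path) -> tuple[Path, Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in {".geno", ".snp", ".ind"} else p
    return (stem.with_suffix(".geno"), stem.with_suffix(".snp"),
            stem.with_suffix(".ind"))


def _read_eigenstrat(path: str | Path, population_label: str) -> GenotypeDataset:
    geno_path, snp_path, ind_path = _eigen_paths(path)
    ind = pd.read_csv(ind_path, sep=r"\s+", header=None,
                      names=["sample", "sex", "label"], dtype=str)
    snp_df = pd.read_csv(snp_path, sep=r"\s+", header=None,
                         names=["snp_id", "chromosome", "position_morgan",
                                "position_bp", "allele_ref", "allele_alt"],
                         dtype={"snp_id": str, "chromosome": str})
    samples = ind["sample"].tolist()
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line and samples:
                continue
            if len(line) != len(samples) or set(line) - set("0129"):
                raise FormatError(
                    f"{geno_path} line {lineno}: bad genotype row")
            rows.append([int(c) for c in line])
    if samples and len(rows) != len(snp_df):
        raise FormatError(
            f"{geno_path}: {len(rows)} rows but {len(snp_df)} SNPs in {snp_path}")
    geno = (np.array(rows, dtype=np.int8).T if rows
            else np.empty((len(samples), 0), dtype=np.int8))
    # .geno digits count reference-allele copies; internal dosage counts alt
    calls = np.where(geno == 9, MISSING, 2 - geno).astype(np.int8)
    records = [
        SnpRecord(r.snp_id, r.chromosome, int(r.position_bp),
                  r.allele_ref, r.allele_alt,
                  float(r.position_morgan) * 100.0)
        for r in snp_df.itertuples()]
    snps = make_snp_table(records)
    col_index = {s: i for i, s in enumerate(snp_df["snp_id"])}
    calls = calls[:, [col_index[s] for s in snps["snp_id"]]]
    return GenotypeDataset(samples, snps, calls, population_label)


def _write_eigenstrat(dataset: GenotypeDataset, path: str | Path) -> None:
    geno_path, snp_path, ind_path = _eigen_paths(path)
    with open(ind_path, "w") as fh:
        label = dataset.population_label or "pop"
        for s in dataset.samples:
            fh.write(f"{s}\tU\t{label}\n")
    with open(snp_path, "w") as fh:
        for row in dataset.snps.itertuples():
            morgan = 0.0 if pd.isna(row.position_cm) else row.position_cm / 100.0
            fh.write(f"{row.snp_id}\t{row.chromosome}\t{morgan!r}\t"
                     f"{row.position_bp}\t{row.allele_ref}\t{row.allele_alt}\n")
    with open(geno_path, "w") as fh:
        for j in range(dataset.n_snps):
            col = dataset.calls[:, j]
            digits = np.where(col == MISSING, 9, 2 - col)
            fh.write("".join(str(int(d)) for d in digits) + "\n")


# ---------------------------------------------------------------------------
# dispatch + harmonization
# ---------------------------------------------------------------------------

_READERS = {"ped": _read_ped, "vcf": _read_vcf, "eigenstrat": _read_eigenstrat}
_WRITERS = {"ped": _write_ped, "vcf": _write_vcf, "eigenstrat": _write_eigenstrat}
FORMATS = tuple(_READERS)


def read_genotypes(path: str | Path, format: str,
                   population_label: str = "") -> GenotypeDataset:
    """Read a genotype dataset from ``path`` in the named format."""
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return _READERS[format](path, population_label)


def write_genotypes(dataset: GenotypeDataset, path: str | Path,
                    format: str) -> None:
    """Write a dataset so that :func:`read_genotypes` recovers it."""
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    _WRITERS[format](dataset, path)


def _is_ambiguous(ref: str, alt: str) -> bool:
    return COMPLEMENT[ref] == alt


def harmonize(datasets: Sequence[GenotypeDataset]) -> list[GenotypeDataset]:
    """Restrict datasets to a shared, consistently oriented SNP set.

    SNPs are matched on ``snp_id``; the first dataset defines the reference
    allele orientation.  At each shared SNP the other datasets may match
    directly, with ref/alt swapped (dosage recoded as ``2 - g``), or on the
    opposite strand (alleles complemented).  Strand-ambiguous A/T and C/G
    SNPs are kept only when the ordered allele pair matches exactly, since a
    swap and a strand flip are indistinguishable there.  Irreconcilable SNPs
    are dropped and counted in the log.
    """
    if len(datasets) < 2:
        raise ValueError("harmonize requires at least two datasets")
    common = set(datasets[0].snps["snp_id"])
    for ds in datasets[1:]:
        common &= set(ds.snps["snp_id"])
    if not common:
        raise ValidationError("no SNPs shared by all datasets")

    first = datasets[0].snps.set_index("snp_id")
    keep: list[str] = []
    flips: list[dict[str, bool]] = [dict() for _ in datasets]
    n_dropped = 0
    for snp_id in datasets[0].snps["snp_id"]:
        if snp_id not in common:
            continue
        ref0, alt0 = first.loc[snp_id, ["allele_ref", "allele_alt"]]
        ok = True
        snp_flip = [False] * len(datasets)
        for k, ds in enumerate(datasets[1:], start=1):
            row = ds.snps.loc[ds.snps["snp_id"] == snp_id].iloc[0]
            ref, alt = row["allele_ref"], row["allele_alt"]
            if (ref, alt) == (ref0, alt0):
                continue
            if _is_ambiguous(ref0, alt0) or _is_ambiguous(ref, alt):
                ok = False  # only exact match accepted for ambiguous pairs
                break
            if (ref, alt) == (alt0, ref0):
                snp_flip[k] = True
            elif (COMPLEMENT[ref], COMPLEMENT[alt]) == (ref0, alt0):
                pass  # strand flip, orientation preserved
            elif (COMPLEMENT[ref], COMPLEMENT[alt]) == (alt0, ref0):
                snp_flip[k] = True
            else:
                ok = False
                break
        if ok:
            keep.append(snp_id)
            for k in range(1, len(datasets)):
                flips[k][snp_id] = snp_flip[k]
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("harmonize: dropped %d SNPs with irreconcilable alleles",
                    n_dropped)
    if not keep:
        raise ValidationError("no SNPs remain after allele reconciliation")

    out = []
    ref_meta = first.loc[keep]
    for k, ds in enumerate(datasets):
        sub = ds.subset_snps(keep)
        # align column order and metadata to the first dataset
        col_index = {s: i for i, s in enumerate(sub.snps["snp_id"])}
        order = [col_index[s] for s in keep]
        calls = sub.calls[:, order].copy()
        if k > 0:
            flip_mask = np.array([flips[k][s] for s in keep])
            cols = calls[:, flip_mask]
            cols[cols != MISSING] = 2 - cols[cols != MISSING]
            calls[:, flip_mask] = cols
        snps = ref_meta.reset_index()[SNP_COLUMNS].copy()
        out.append(GenotypeDataset(list(sub.samples), snps, calls,
                                   ds.population_label))
    return out
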