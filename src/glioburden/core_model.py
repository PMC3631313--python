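"""Domain types and file readers/writers for the glioma burden pipeline.

Every file the pipeline touches goes through this module: annotated variant
tables (TSV dialect or VCF), sample metadata, methylation beta matrices with
probe annotations, and densitometry tables. Validation is strict — a
malformed row fails with the file, line number and offending token — and
``read`` / ``write`` are exact inverses on valid data.

Genomic coordinates follow the VCF convention (1-based, explicit ref/alt
alleles); nothing downstream re-interprets them. Consequence classes and
SIFT/PolyPhen-2 calls are consumed as upstream annotations, never computed.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Consequence",
    "SiftCall",
    "PolyphenCall",
    "Arm",
    "Grade",
    "AgeGroup",
    "Location",
    "GeneStatus",
    "VariantRecord",
    "SampleMeta",
    "GeneBurdenResult",
    "BetaMatrix",
    "ConsensusResult",
    "DensitometryTable",
    "ValidationError",
    "read_variants",
    "write_variants",
    "read_metadata",
    "write_metadata",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotations",
    "write_probe_annotations",
    "read_densitometry",
    "write_densitometry",
    "VARIANT_COLUMNS",
    "METADATA_COLUMNS",
    "VCF_INFO_KEYS",
]


class ValidationError(ValueError):
    """Raised when an input file or record fails validation.

    The message always names the offending file (when applicable), line
    number and token so that broken inputs can be located directly.
    """


# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

class Consequence(enum.StrEnum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class SiftCall(enum.StrEnum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class PolyphenCall(enum.StrEnum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class Arm(enum.StrEnum):
    TUMOR = "tumor"
    CONTROL = "control"


class Grade(enum.StrEnum):
    II = "II"
    III = "III"
    IV = "IV"
    NA = "NA"


class AgeGroup(enum.StrEnum):
    PEDIATRIC = "pediatric"
    ADULT = "adult"
    NA = "NA"


class Location(enum.StrEnum):
    HEMISPHERIC = "hemispheric"
    MIDLINE = "midline"
    OTHER = "other"
    NA = "NA"


class GeneStatus(enum.StrEnum):
    MUTATED = "mutated"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"


def _parse_enum(cls, token: str, *, where: str):
    try:
        return cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"{where}: unknown {cls.__name__} token {token!r} (allowed: {allowed})"
        ) from None


def _parse_bool(token: str, *, where: str) -> bool:
    if token == "1":
        return True
    if token == "0":
        return False
    raise ValidationError(f"{where}: expected boolean 0/1, got {token!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call in one sample.

    ``in_population_db`` marks presence in 1000 Genomes or the NHLBI exome
    database; ``in_control_exomes`` marks presence in any control exome.
    A variant absent from all three sources is *private* and treated as a
    candidate somatic mutation. ``conserved`` records whether the affected
    residue is highly conserved in vertebrates (annotated upstream).
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    sift: SiftCall
    polyphen: PolyphenCall
    conserved: bool
    in_population_db: bool
    in_control_exomes: bool

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.sample_id}/{self.gene}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"variant {self.sample_id}/{self.gene} at {self.chrom}:{self.pos}: ref == alt ({self.ref!r})"
            )


@dataclass(frozen=True)
class SampleMeta:
    """One tumor or control sample with its clinical strata.

    Control samples carry no tumor grade or brain location (``NA``).
    ``gene_status`` maps tracked gene symbols to mutated/wildtype/unknown;
    unknown means the gene was not assayed in that sample.
    """

    sample_id: str
    arm: Arm
    grade: Grade = Grade.NA
    age_group: AgeGroup = AgeGroup.NA
    age_years: float | None = None
    location: Location = Location.NA
    gene_status: Mapping[str, GeneStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm is Arm.CONTROL and (self.grade is not Grade.NA or self.location is not Location.NA):
            raise ValidationError(
                f"sample {self.sample_id}: control samples must have grade/location NA"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError(f"sample {self.sample_id}: age_years must be >= 0")


@dataclass(frozen=True)
class GeneBurdenResult:
    """Per-gene 2x2 burden test result.

    ``a``/``b`` are tumor carriers / non-carriers, ``c``/``d`` control
    carriers / non-carriers. ``p`` is the two-sided exact test p-value, ``q``
    its Benjamini–Hochberg adjusted value over the configured gene universe.
    """

    gene: str
    a: int
    b: int
    c: int
    d: int
    p: float
    q: float
    rank: int
    mode: str

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValidationError(f"gene {self.gene}: cell {name} negative")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"gene {self.gene}: p={self.p} outside (0,1]")
        if not (0.0 < self.q <= 1.0) or self.q < self.p - 1e-12:
            raise ValidationError(f"gene {self.gene}: q={self.q} invalid (p={self.p})")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with per-probe annotations.

    ``beta`` holds methylation fractions in [0, 1] (rows = probes, columns =
    samples). ``probe_annotations`` is a DataFrame indexed by probe_id with
    columns ``chrom`` (string), ``cross_reactive`` (bool) and ``snp_maf``
    (minor-allele frequency of any variant in the probe binding region, NaN
    when none is known).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    beta: np.ndarray
    probe_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta shape {self.beta.shape} does not match {len(self.probe_ids)} probes x "
                f"{len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicated probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample ids")
        bad = ~np.isfinite(self.beta) | (self.beta < 0.0) | (self.beta > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {self.beta[i, j]!r} out of [0,1] at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.probe_ids, columns=self.sample_ids)

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [idx[p] for p in probe_ids]
        ann = None
        if self.probe_annotations is not None:
            ann = self.probe_annotations.loc[list(probe_ids)]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.beta[rows, :], ann)


@dataclass
class ConsensusResult:
    """Consensus clustering output across a range of cluster numbers k.

    ``consensus[k]`` is the sample x sample co-clustering frequency matrix
    (symmetric, unit diagonal, entries in [0,1]); ``A[k]`` the area under the
    empirical CDF of its upper-triangle entries; ``delta[k]`` the relative
    area increase used for model selection; ``labels[k]`` the per-sample
    cluster assignment obtained by cutting the consensus dendrogram at k.
    """

    k_values: list[int]
    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    A: dict[int, float] = field(default_factory=dict)
    delta: dict[int, float] = field(default_factory=dict)
    selected_k: int | None = None

    def __post_init__(self) -> None:
        for k, m in self.consensus.items():
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValidationError(f"consensus matrix for k={k} not symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValidationError(f"consensus matrix for k={k} diagonal != 1")
            if (m < -1e-12).any() or (m > 1 + 1e-12).any():
                raise ValidationError(f"consensus matrix for k={k} has entries outside [0,1]")


@dataclass(frozen=True)
class DensitometryTable:
    """Densitometry intensities for one (blot, sample) band pair."""

    blot_id: str
    sample_id: str
    group: str  # "setd2_mutant" or "wildtype_star"
    h3k36me3: float
    h3_total: float

    def __post_init__(self) -> None:
        if self.h3k36me3 < 0:
            raise ValidationError(
                f"blot {self.blot_id}, sample {self.sample_id}: negative H3K36me3 intensity"
            )
        if not self.h3_total > 0:
            raise ValidationError(
                f"blot {self.blot_id}, sample {self.sample_id}: H3 total must be > 0 "
                f"(got {self.h3_total}); ratio undefined"
            )


# ---------------------------------------------------------------------------
# Variant table I/O
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "consequence", "sift", "polyphen",
    "conserved", "in_population_db", "in_control_exomes",
]

#: VCF INFO keys carrying the per-variant annotations.
VCF_INFO_KEYS = {
    "gene": "GENE",
    "consequence": "CSQCLASS",
    "sift": "SIFT",
    "polyphen": "PPH2",
    "conserved": "CONS",
    "in_population_db": "POPDB",
    "in_control_exomes": "CTRLDB",
}


def _variant_from_tokens(tokens: Mapping[str, str], where: str) -> VariantRecord:
    try:
        pos = int(tokens["pos"])
    except ValueError:
        raise ValidationError(f"{where}: pos {tokens['pos']!r} is not an integer") from None
    return VariantRecord(
        sample_id=tokens["sample_id"],
        gene=tokens["gene"],
        chrom=tokens["chrom"],
        pos=pos,
        ref=tokens["ref"],
        alt=tokens["alt"],
        consequence=_parse_enum(Consequence, tokens["consequence"], where=where),
        sift=_parse_enum(SiftCall, tokens["sift"], where=where),
        polyphen=_parse_enum(PolyphenCall, tokens["polyphen"], where=where),
        conserved=_parse_bool(tokens["conserved"], where=where),
        in_population_db=_parse_bool(tokens["in_population_db"], where=where),
        in_control_exomes=_parse_bool(tokens["in_control_exomes"], where=where),
    )


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(_strip_comments(fh), delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected header") from None
        if header != VARIANT_COLUMNS:
            raise ValidationError(
                f"{path}, line 1: bad header {header!r}; expected {VARIANT_COLUMNS!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(VARIANT_COLUMNS):
                raise ValidationError(
                    f"{path}, line {lineno}: expected {len(VARIANT_COLUMNS)} columns, got {len(row)}"
                )
            where = f"{path}, line {lineno}"
            records.append(_variant_from_tokens(dict(zip(VARIANT_COLUMNS, row)), where))
    return records


def _strip_comments(lines: Iterable[str]) -> Iterable[str]:
    for line in lines:
        if not line.startswith("#"):
            yield line


def _info_token(variant, key: str, where: str) -> str:
    val = variant.INFO.get(key)
    if val is None:
        raise ValidationError(f"{where}: missing INFO key {key}")
    return str(val)


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        where = f"{path}, {v.CHROM}:{v.POS}"
        common = dict(
            gene=_info_token(v, VCF_INFO_KEYS["gene"], where),
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0] if v.ALT else ".",
            consequence=_parse_enum(Consequence, _info_token(v, VCF_INFO_KEYS["consequence"], where), where=where),
            sift=_parse_enum(SiftCall, _info_token(v, VCF_INFO_KEYS["sift"], where), where=where),
            polyphen=_parse_enum(PolyphenCall, _info_token(v, VCF_INFO_KEYS["polyphen"], where), where=where),
            conserved=_info_token(v, VCF_INFO_KEYS["conserved"], where) not in ("0", "False"),
            in_population_db=_info_token(v, VCF_INFO_KEYS["in_population_db"], where) not in ("0", "False"),
            in_control_exomes=_info_token(v, VCF_INFO_KEYS["in_control_exomes"], where) not in ("0", "False"),
        )
        # one record per carrier sample: any genotype with a non-ref allele
        types = v.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sample, gt in zip(sample_names, types):
            if gt in (1, 3):
                records.append(VariantRecord(sample_id=sample, **common))
    return records


def read_variants(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    """Read annotated variants from a TSV table or an annotated VCF.

    TSV dialect: tab-separated with the header ``sample_id gene chrom pos
    ref alt consequence sift polyphen conserved in_population_db
    in_control_exomes`` and booleans encoded ``0``/``1``. VCF: standard 4.x
    with annotations in INFO keys GENE, CSQCLASS, SIFT, PPH2, CONS, POPDB,
    CTRLDB; a multi-sample VCF expands to one record per carrier sample.

    Row order is preserved; every record is validated on construction.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    if format == "tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    raise ValidationError(f"unknown variant format {format!r} (allowed: tsv, vcf)")


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write variants in the TSV dialect (inverse of ``read_variants``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for r in records:
            w.writerow([
                r.sample_id, r.gene, r.chrom, r.pos, r.ref, r.alt,
                r.consequence.value, r.sift.value, r.polyphen.value,
                int(r.conserved), int(r.in_population_db), int(r.in_control_exomes),
            ])


# ---------------------------------------------------------------------------
# Sample metadata I/O
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "arm", "grade", "age_group", "age_years", "location"]


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata; columns beyond the fixed six are per-gene statuses.

    Header: ``sample_id arm grade age_group age_years location`` followed by
    one column per tracked gene symbol with values mutated/wildtype/unknown.
    Missing optional fields (empty or ``NA``) become NA. Duplicate sample ids
    are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    samples: list[SampleMeta] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(_strip_comments(fh), delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected header") from None
        if header[: len(METADATA_COLUMNS)] != METADATA_COLUMNS:
            raise ValidationError(
                f"{path}, line 1: header must start with {METADATA_COLUMNS!r}, got {header!r}"
            )
        genes = header[len(METADATA_COLUMNS):]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}, line {lineno}: expected {len(header)} columns, got {len(row)}"
                )
            where = f"{path}, line {lineno}"
            tokens = dict(zip(header, row))
            sid = tokens["sample_id"]
            if sid in seen:
                raise ValidationError(f"{where}: duplicated sample_id {sid!r}")
            seen.add(sid)
            age_tok = tokens["age_years"]
            age = None if age_tok in ("", "NA") else _parse_age(age_tok, where)
            status = {
                g: _parse_enum(GeneStatus, tokens[g] or "unknown", where=where) for g in genes
            }
            samples.append(SampleMeta(
                sample_id=sid,
                arm=_parse_enum(Arm, tokens["arm"], where=where),
                grade=_parse_enum(Grade, tokens["grade"] or "NA", where=where),
                age_group=_parse_enum(AgeGroup, tokens["age_group"] or "NA", where=where),
                age_years=age,
                location=_parse_enum(Location, tokens["location"] or "NA", where=where),
                gene_status=status,
            ))
    return samples


def _parse_age(token: str, where: str) -> float:
    try:
        age = float(token)
    except ValueError:
        raise ValidationError(f"{where}: age_years {token!r} is not a number or NA") from None
    if not math.isfinite(age) or age < 0:
        raise ValidationError(f"{where}: age_years {token!r} must be finite and >= 0")
    return age


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    """Write metadata TSV (inverse of ``read_metadata``).

    The gene-status column set is the union over samples, sorted; a sample
    lacking a tracked gene writes ``unknown``.
    """
    genes = sorted({g for s in samples for g in s.gene_status})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(METADATA_COLUMNS + genes)
        for s in samples:
            age = "NA" if s.age_years is None else format(s.age_years, "g")
            w.writerow(
                [s.sample_id, s.arm.value, s.grade.value, s.age_group.value, age, s.location.value]
                + [s.gene_status.get(g, GeneStatus.UNKNOWN).value for g in genes]
            )


# ---------------------------------------------------------------------------
# Beta matrix and probe annotation I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path: str | Path,
    annotations: str | Path | None = None,
    sep: str = "\t",
) -> BetaMatrix:
    """Read a probes x samples beta matrix (first column ``probe_id``).

    Out-of-range values are an error, not clipped: betas are methylation
    fractions and anything outside [0, 1] indicates a broken upstream
    normalization. The error names the probe and sample.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "probe_id":
        raise ValidationError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    values = df.to_numpy(dtype=float)
    ann = read_probe_annotations(annotations) if annotations is not None else None
    try:
        return BetaMatrix(list(df.index), list(df.columns), values, ann)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


def write_beta_matrix(bm: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the beta matrix TSV with full float precision (round-trip exact)."""
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(["probe_id", *bm.sample_ids]) + "\n")
        for pid, row in zip(bm.probe_ids, bm.beta):
            fh.write(pid + sep + sep.join(repr(float(x)) for x in row) + "\n")


def read_probe_annotations(path: str | Path) -> pd.DataFrame:
    """Read probe annotations: ``probe_id chrom cross_reactive snp_maf``.

    ``snp_maf`` may be ``NA`` (no known variant in the probe binding region).
    Returns a DataFrame indexed by probe_id.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    expected = ["probe_id", "chrom", "cross_reactive", "snp_maf"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: header must be {expected!r}, got {list(df.columns)!r}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated probe_id {dup!r}")
    df = df.set_index("probe_id")
    df["cross_reactive"] = df["cross_reactive"].astype(bool)
    df["snp_maf"] = pd.to_numeric(df["snp_maf"], errors="coerce")
    bad = df["snp_maf"].dropna()
    bad = bad[(bad < 0) | (bad > 1)]
    if len(bad):
        raise ValidationError(f"{path}: snp_maf {bad.iloc[0]} out of [0,1] for probe {bad.index[0]!r}")
    return df


def write_probe_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.reset_index()
    out["cross_reactive"] = out["cross_reactive"].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Densitometry I/O
# ---------------------------------------------------------------------------

DENSITOMETRY_COLUMNS = ["blot_id", "sample_id", "group", "h3k36me3", "h3_total"]
DENSITOMETRY_GROUPS = ("setd2_mutant", "wildtype_star")


def read_densitometry(path: str | Path) -> list[DensitometryTable]:
    """Read a densitometry table: ``blot_id sample_id group h3k36me3 h3_total``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    rows: list[DensitometryTable] = []
    with open(path, newline="") as fh:
        reader = csv.reader(_strip_comments(fh), delimiter="\t")
        header = next(reader, None)
        if header != DENSITOMETRY_COLUMNS:
            raise ValidationError(f"{path}, line 1: header must be {DENSITOMETRY_COLUMNS!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            where = f"{path}, line {lineno}"
            if len(row) != 5:
                raise ValidationError(f"{where}: expected 5 columns, got {len(row)}")
            blot, sid, group, me3, h3 = row
            if group not in DENSITOMETRY_GROUPS:
                raise ValidationError(
                    f"{where}: unknown group {group!r} (allowed: {', '.join(DENSITOMETRY_GROUPS)})"
                )
            try:
                rows.append(DensitometryTable(blot, sid, group, float(me3), float(h3)))
            except ValueError:
                raise ValidationError(f"{where}: non-numeric intensity") from None
    return rows


def write_densitometry(rows: Sequence[DensitometryTable], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DENSITOMETRY_COLUMNS)
        for r in rows:
            w.writerow([r.blot_id, r.sample_id, r.group, repr(float(r.h3k36me3)), repr(float(r.h3_total))])
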