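"""Synthetic cohorts with known ground truth, plus transcribed table fixtures.

Three generators feed the pipeline's stages with inputs whose truth is known
by construction:

* ``simulate_variant_cohort`` — tumor/control exome cohorts with per-gene
  Poisson background mutation rates, database-membership decoys, and
  optional injected driver genes with an elevated tumor-only rate and a
  truncating excess;
* ``simulate_beta_matrix`` — clustered methylation beta matrices with
  configurable cluster separation and noise;
* ``simulate_densitometry`` — replicate-blot densitometry tables with a
  group-level shift in the H3K36me3 / total-H3 ratio.

``fixture_table1`` reconstructs, cell by cell, the published 183-sample
glioma cohort's SETD2 mutation-frequency table (grade x age group); it is
also shipped as a packaged TSV. All generators are deterministic: one
explicitly seeded pseudo-random stream per call, no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_model import (
    AgeGroup,
    Arm,
    BetaMatrix,
    Consequence,
    DensitometryTable,
    GeneStatus,
    Grade,
    Location,
    PolyphenCall,
    SampleMeta,
    SiftCall,
    ValidationError,
    VariantRecord,
)

__all__ = [
    "DriverSpec",
    "CohortSimSpec",
    "BetaSimSpec",
    "DensitometrySimSpec",
    "simulate_variant_cohort",
    "simulate_beta_matrix",
    "simulate_densitometry",
    "fixture_table1",
    "fixture_setd2_variants",
    "fixture_discovery_metadata",
    "packaged_fixture_path",
]


# ---------------------------------------------------------------------------
# Simulation specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriverSpec:
    """An injected driver gene: tumor-only rate elevation and truncating excess."""

    gene: str
    rate_multiplier: float
    truncating_fraction: float

    def __post_init__(self) -> None:
        if self.rate_multiplier < 0:
            raise ValidationError("rate_multiplier must be >= 0")
        if not (0.0 <= self.truncating_fraction <= 1.0):
            raise ValidationError("truncating_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a simulated tumor/control exome cohort.

    ``background_rate`` is the expected number of *kept* variants (private
    and predicted damaging) per gene per sample, identical in both arms; the
    default 1e-2 matches the per-gene private-variant rate observed in large
    control-exome sets (order 10^2 private damaging variants per exome over
    ~2x10^4 genes, with large genes reaching ~1.3e-2). The generator also
    emits decoy variants that the filter must remove: database-flagged
    copies at ``db_flag_rate`` and missense calls that both predictors score
    non-damaging at ``missense_nondamaging_fraction``. Drivers add private
    damaging variants in tumors only, at ``background_rate * (multiplier-1)``
    with their own truncating fraction.
    """

    n_tumor: int = 60
    n_control: int = 543
    n_genes: int = 200
    background_rate: float = 1e-2
    drivers: tuple[DriverSpec, ...] = ()
    db_flag_rate: float = 0.3
    background_truncating_fraction: float = 0.05
    missense_nondamaging_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_control < 1 or self.n_genes < 1:
            raise ValidationError("cohort dimensions must be >= 1")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be >= 0")
        for frac in (self.db_flag_rate, self.background_truncating_fraction,
                     self.missense_nondamaging_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError("fractions must be in [0, 1]")
        known = {f"G{i + 1:04d}" for i in range(self.n_genes)}
        for drv in self.drivers:
            if drv.gene not in known:
                raise ValidationError(f"driver gene {drv.gene!r} outside simulated universe")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class BetaSimSpec:
    """Parameters of a clustered methylation beta matrix.

    Cluster structure lives on ``n_informative_probes`` probes split evenly
    among the ``k_true`` clusters: each informative block sits at 0.5 +
    ``shift`` in its own cluster and 0.5 - ``shift`` elsewhere. Remaining
    probes are constant-mean noise. Betas are clipped to [0.001, 0.999].
    """

    n_samples: int = 60
    n_probes: int = 500
    k_true: int = 3
    n_informative_probes: int = 100
    shift: float = 0.25
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shift <= 1.0):
            raise ValidationError("shift must be in [0, 1]")
        if self.k_true > self.n_samples / 3:
            raise ValidationError("k_true must be <= n_samples / 3")
        if self.n_informative_probes > self.n_probes:
            raise ValidationError("n_informative_probes exceeds n_probes")


@dataclass(frozen=True)
class DensitometrySimSpec:
    """Replicate-blot densitometry with a group shift in the normalized ratio.

    The wildtype group ratio is centred at ``base_ratio``; the SETD2-mutant
    group at ``base_ratio - shift_sds * noise_sd`` (a loss of H3K36me3).
    ``noise_sd`` is per-blot measurement noise; four replicate blots per
    sample by default.
    """

    n_per_group: int = 6
    n_blots: int = 4
    base_ratio: float = 1.0
    shift_sds: float = 3.0
    noise_sd: float = 0.15
    seed: int = 0


# ---------------------------------------------------------------------------
# Variant cohort generator
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _make_variant(rng: np.random.Generator, sample_id: str, gene: str, gene_idx: int,
                  consequence: Consequence, sift: SiftCall, polyphen: PolyphenCall,
                  conserved: bool, popdb: bool, ctrldb: bool) -> VariantRecord:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
    return VariantRecord(
        sample_id=sample_id,
        gene=gene,
        chrom=str(1 + gene_idx % 22),
        pos=int(1000 * (gene_idx + 1) + rng.integers(1, 1000)),
        ref=ref,
        alt=alt,
        consequence=consequence,
        sift=sift,
        polyphen=polyphen,
        conserved=conserved,
        in_population_db=popdb,
        in_control_exomes=ctrldb,
    )


def _background_variant(rng: np.random.Generator, spec: CohortSimSpec,
                        sample_id: str, gene: str, gene_idx: int) -> VariantRecord:
    popdb = bool(rng.random() < spec.db_flag_rate)
    if rng.random() < spec.background_truncating_fraction:
        csq = Consequence(rng.choice([Consequence.NONSENSE, Consequence.FRAMESHIFT,
                                      Consequence.SPLICE_SITE]))
        sift, pph = SiftCall.UNKNOWN, PolyphenCall.UNKNOWN
    else:
        csq = Consequence.MISSENSE
        if rng.random() < spec.missense_nondamaging_fraction:
            sift = SiftCall(rng.choice([SiftCall.TOLERATED, SiftCall.UNKNOWN]))
            pph = PolyphenCall(rng.choice([PolyphenCall.BENIGN, PolyphenCall.UNKNOWN]))
        else:
            # at least one predictor damaging
            which = rng.integers(3)
            sift = SiftCall.DAMAGING if which in (0, 2) else SiftCall.TOLERATED
            pph = PolyphenCall.DAMAGING if which in (1, 2) else PolyphenCall.BENIGN
    return _make_variant(rng, sample_id, gene, gene_idx, csq, sift, pph,
                         conserved=bool(rng.random() < 0.5), popdb=popdb, ctrldb=False)


def _driver_variant(rng: np.random.Generator, drv: DriverSpec,
                    sample_id: str, gene_idx: int) -> VariantRecord:
    if rng.random() < drv.truncating_fraction:
        csq = Consequence(rng.choice([Consequence.NONSENSE, Consequence.FRAMESHIFT,
                                      Consequence.SPLICE_SITE]))
        sift, pph = SiftCall.UNKNOWN, PolyphenCall.UNKNOWN
    else:
        csq, sift, pph = Consequence.MISSENSE, SiftCall.DAMAGING, PolyphenCall.DAMAGING
    return _make_variant(rng, sample_id, drv.gene, gene_idx, csq, sift, pph,
                         conserved=True, popdb=False, ctrldb=False)


def simulate_variant_cohort(
    spec: CohortSimSpec,
) -> tuple[list[VariantRecord], list[SampleMeta], dict]:
    """Simulate an annotated tumor/control variant cohort.

    Background variant counts per sample x gene are Poisson with a raw rate
    inflated so that the *kept* rate (after the private/damaging cascade)
    equals ``spec.background_rate`` in expectation. Driver genes receive
    additional private damaging variants in tumor samples only. Returns
    ``(variants, metadata, truth)`` where truth records the driver genes and
    the effective rates used.
    """
    rng = np.random.default_rng(spec.seed)
    p_damaging = (spec.background_truncating_fraction
                  + (1 - spec.background_truncating_fraction)
                  * (1 - spec.missense_nondamaging_fraction))
    p_keep = (1 - spec.db_flag_rate) * p_damaging
    raw_rate = spec.background_rate / p_keep if p_keep > 0 else 0.0
    genes = spec.gene_names
    driver_by_gene = {d.gene: d for d in spec.drivers}

    tumor_ids = [f"T{i + 1:04d}" for i in range(spec.n_tumor)]
    control_ids = [f"C{i + 1:04d}" for i in range(spec.n_control)]

    variants: list[VariantRecord] = []
    for sid, is_tumor in [(s, True) for s in tumor_ids] + [(s, False) for s in control_ids]:
        for gi, gene in enumerate(genes):
            for _ in range(rng.poisson(raw_rate)):
                variants.append(_background_variant(rng, spec, sid, gene, gi))
            if is_tumor and gene in driver_by_gene:
                drv = driver_by_gene[gene]
                extra = spec.background_rate * max(drv.rate_multiplier - 1.0, 0.0)
                for _ in range(rng.poisson(extra)):
                    variants.append(_driver_variant(rng, driver_by_gene[gene], sid, gi))

    tracked = sorted(driver_by_gene)
    metadata: list[SampleMeta] = []
    mutated = {g: {v.sample_id for v in variants
                   if v.gene == g and not v.in_population_db and not v.in_control_exomes}
               for g in tracked}
    for i, sid in enumerate(tumor_ids):
        metadata.append(SampleMeta(
            sample_id=sid,
            arm=Arm.TUMOR,
            grade=Grade.IV if i % 6 != 5 else Grade.III,  # ~85 % grade IV, as in pediatric HGG series
            age_group=AgeGroup.PEDIATRIC,
            age_years=float(1 + i % 20),
            location=Location.HEMISPHERIC if i % 3 != 2 else Location.MIDLINE,
            gene_status={g: (GeneStatus.MUTATED if sid in mutated[g] else GeneStatus.WILDTYPE)
                         for g in tracked},
        ))
    for sid in control_ids:
        metadata.append(SampleMeta(
            sample_id=sid,
            arm=Arm.CONTROL,
            gene_status={g: GeneStatus.WILDTYPE for g in tracked},
        ))

    truth = {
        "drivers": [d.gene for d in spec.drivers],
        "background_kept_rate": spec.background_rate,
        "raw_rate": raw_rate,
        "p_keep_background": p_keep,
        "driver_extra_rate": {d.gene: spec.background_rate * max(d.rate_multiplier - 1.0, 0.0)
                              for d in spec.drivers},
    }
    return variants, metadata, truth


# ---------------------------------------------------------------------------
# Beta matrix generator
# ---------------------------------------------------------------------------

def simulate_beta_matrix(spec: BetaSimSpec) -> tuple[BetaMatrix, np.ndarray]:
    """Simulate a clustered beta matrix; returns the matrix and true labels.

    Samples are assigned to the ``k_true`` clusters round-robin (balanced).
    Informative probes are split evenly among clusters; probe block j is
    centred at 0.5 + shift for cluster-j samples and 0.5 - shift otherwise.
    Gaussian noise with ``noise_sd`` is added everywhere and values clipped
    to [0.001, 0.999]. Probe annotations are all-pass (autosomal, not
    cross-reactive, no binding SNP).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n_samples) % spec.k_true
    probe_ids = [f"cg{i + 1:06d}" for i in range(spec.n_probes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]

    means = np.full((spec.n_probes, spec.n_samples), 0.5)
    block = spec.n_informative_probes // spec.k_true
    for j in range(spec.k_true):
        lo = j * block
        hi = spec.n_informative_probes if j == spec.k_true - 1 else (j + 1) * block
        in_cluster = labels == j
        means[lo:hi, in_cluster] = 0.5 + spec.shift / 2.0
        means[lo:hi, ~in_cluster] = 0.5 - spec.shift / 2.0

    beta = np.clip(means + rng.normal(0.0, spec.noise_sd, means.shape), 0.001, 0.999)
    ann = pd.DataFrame(
        {"chrom": "1", "cross_reactive": False, "snp_maf": np.nan}, index=probe_ids
    )
    ann.index.name = "probe_id"
    return BetaMatrix(probe_ids, sample_ids, beta, ann), labels


# ---------------------------------------------------------------------------
# Densitometry generator
# ---------------------------------------------------------------------------

def simulate_densitometry(spec: DensitometrySimSpec) -> list[DensitometryTable]:
    """Simulate replicate-blot densitometry for mutant vs wildtype samples."""
    rng = np.random.default_rng(spec.seed)
    rows: list[DensitometryTable] = []
    mutant_mean = spec.base_ratio - spec.shift_sds * spec.noise_sd
    for group, mean in (("setd2_mutant", mutant_mean), ("wildtype_star", spec.base_ratio)):
        for i in range(spec.n_per_group):
            sid = f"{'MUT' if group == 'setd2_mutant' else 'WT'}{i + 1:02d}"
            for b in range(spec.n_blots):
                h3 = float(rng.uniform(0.8, 1.2))
                ratio = max(mean + rng.normal(0.0, spec.noise_sd), 0.0)
                rows.append(DensitometryTable(f"blot{b + 1}", sid, group, ratio * h3, h3))
    return rows


# ---------------------------------------------------------------------------
# Fixtures transcribed from the published cohort tables
# ---------------------------------------------------------------------------

#: (grade, age_group, mutated, wildtype) cells of the published 183-sample
#: SETD2 frequency table. Per-grade and overall totals are derived sums.
_TABLE1_CELLS: tuple[tuple[Grade, AgeGroup, int, int], ...] = (
    (Grade.IV, AgeGroup.PEDIATRIC, 9, 51),
    (Grade.IV, AgeGroup.ADULT, 3, 34),
    (Grade.III, AgeGroup.PEDIATRIC, 2, 11),
    (Grade.III, AgeGroup.ADULT, 2, 26),
    (Grade.II, AgeGroup.PEDIATRIC, 0, 23),
    (Grade.II, AgeGroup.ADULT, 0, 22),
)


def fixture_table1() -> list[SampleMeta]:
    """Deterministic 183-sample metadata reproducing the published strata.

    Every grade x age-group x SETD2-status cell matches the printed table.
    All mutant tumors are placed in the cerebral hemispheres, as reported;
    wild-type locations are NOT printed in the source and are filled by a
    synthetic alternating hemispheric/midline rule — location-based p-values
    on this fixture are therefore illustrative only. Ages are deterministic
    placeholders within the stated ranges. H3F3A/IDH1 statuses are left
    unknown (per-sample assignments are not printed).
    """
    samples: list[SampleMeta] = []
    i = 0
    for grade, ag, n_mut, n_wt in _TABLE1_CELLS:
        for status, count in ((GeneStatus.MUTATED, n_mut), (GeneStatus.WILDTYPE, n_wt)):
            for j in range(count):
                i += 1
                if status is GeneStatus.MUTATED:
                    loc = Location.HEMISPHERIC
                else:
                    # synthetic reconstruction: unprinted wild-type locations alternate
                    loc = Location.HEMISPHERIC if j % 2 == 0 else Location.MIDLINE
                age = float(5 + j % 15) if ag is AgeGroup.PEDIATRIC else float(25 + j % 40)
                samples.append(SampleMeta(
                    sample_id=f"GLI{i:04d}",
                    arm=Arm.TUMOR,
                    grade=grade,
                    age_group=ag,
                    age_years=age,
                    location=loc,
                    gene_status={
                        "SETD2": status,
                        "H3F3A": GeneStatus.UNKNOWN,
                        "IDH1": GeneStatus.UNKNOWN,
                    },
                ))
    assert len(samples) == 183
    return samples


#: The eight private SETD2 variants observed in the 60 discovery tumors:
#: 3 frameshift, 1 nonsense, 1 splice-site and 3 missense at highly
#: conserved residues, damaging by both predictors. Coordinates are
#: synthetic placeholders on chromosome 3 (per-variant positions are not
#: printed in the source); classes and counts are the published ones.
_SETD2_FIXTURE_ROWS: tuple[tuple[str, int, Consequence], ...] = (
    ("T0001", 47100001, Consequence.FRAMESHIFT),
    ("T0002", 47105002, Consequence.FRAMESHIFT),
    ("T0003", 47110003, Consequence.FRAMESHIFT),
    ("T0004", 47115004, Consequence.NONSENSE),
    ("T0005", 47120005, Consequence.SPLICE_SITE),
    ("T0006", 47125006, Consequence.MISSENSE),
    ("T0007", 47130007, Consequence.MISSENSE),
    ("T0008", 47135008, Consequence.MISSENSE),
)


def fixture_setd2_variants() -> list[VariantRecord]:
    """The eight-tumor SETD2 variant set of the discovery cohort (synthetic coordinates)."""
    out = []
    for sid, pos, csq in _SETD2_FIXTURE_ROWS:
        truncating = csq is not Consequence.MISSENSE
        out.append(VariantRecord(
            sample_id=sid,
            gene="SETD2",
            chrom="3",
            pos=pos,
            ref="C",
            alt="T",
            consequence=csq,
            sift=SiftCall.UNKNOWN if truncating else SiftCall.DAMAGING,
            polyphen=PolyphenCall.UNKNOWN if truncating else PolyphenCall.DAMAGING,
            conserved=not truncating,
            in_population_db=False,
            in_control_exomes=False,
        ))
    return out


def fixture_discovery_metadata() -> list[SampleMeta]:
    """60 tumor + 543 control samples matching the discovery-cohort arms."""
    meta = [
        SampleMeta(
            sample_id=f"T{i + 1:04d}",
            arm=Arm.TUMOR,
            grade=Grade.IV if i < 51 else Grade.III,
            age_group=AgeGroup.PEDIATRIC,
            age_years=float(1 + i % 20),
        )
        for i in range(60)
    ]
    meta += [SampleMeta(sample_id=f"C{i + 1:04d}", arm=Arm.CONTROL) for i in range(543)]
    return meta


def packaged_fixture_path(name: str) -> Path:
    """Path of a packaged fixture TSV (``fixture_table1.tsv`` or ``setd2_variants.tsv``)."""
    p = resources.files("glioburden").joinpath("data", name)
    return Path(str(p))
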