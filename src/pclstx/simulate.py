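"""Seeded synthetic RNA-seq study generator.

Emulates the statistical structure of the two-species PCLS steatosis
experiment so that every downstream stage (QC, paired differential
expression, sign scoring, cross-species concordance) can be exercised and
validated against known ground truth:

* a balanced factorial design per species (subjects x 8 media x 2 timepoints);
* dominant between-donor variance in the human arm versus design-driven
  (time/medium) variance in the mouse arm;
* four planted gene classes — ``null`` (no signal), ``time`` (regulated by
  time in culture identically in all media), ``shared_nutrient``
  (dose-responsive with the same sign in both species) and
  ``divergent_nutrient`` (dose-responsive with opposite signs);
* negative-binomial counts with a log-normal library-size model;
* optionally injected outlier samples carrying a large gene-wise shift.

Every random draw flows from a single integer seed, so identical
configuration gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import (
    MEDIA,
    MEDIUM_ORDER,
    TIMEPOINTS,
    ContrastSpec,
    HUMAN_DONORS,
    MOUSE_SUBJECTS,
    enumerate_design,
)

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "SimulatedStudy",
    "DOSE_TABLE",
    "dose_score",
    "simulate_experiment",
    "simulate_study",
    "simulate_ortholog_map",
]

GENE_CLASSES = ("null", "time", "shared_nutrient", "divergent_nutrient")

#: Default dose model: one unit per supplement component added beyond the
#: 25 mM glucose control (G or F = 1, GF = 2, GFI = 3, GFIO/GFIP = 4,
#: GFIPO = 5).  The assay adds nutrients incrementally but reports no
#: quantitative dose-response, so a component count is the neutral choice.
DOSE_TABLE: dict[str, float] = {
    "CTR": 0.0,
    "G": 1.0,
    "F": 1.0,
    "GF": 2.0,
    "GFI": 3.0,
    "GFIO": 4.0,
    "GFIP": 4.0,
    "GFIPO": 5.0,
}


def dose_score(medium: str, table: dict[str, float] | None = None) -> float:
    """Nutrient load of a medium, used to scale planted nutrient effects.

    Monotone non-decreasing along the supplementation order
    CTR -> G/F -> GF -> GFI -> GFIO/GFIP -> GFIPO, with CTR at 0.
    """
    tbl = DOSE_TABLE if table is None else table
    if medium not in tbl:
        raise KeyError(f"unknown medium {medium!r}")
    return tbl[medium]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Log-scale parameters are in log2 units.  ``nutrient_effect_size`` is the
    planted log2 effect per dose step, so a dose-1 medium (G or F) carries
    exactly that effect and GFIPO carries five times it.
    """

    n_genes: int = 2000
    n_human_subjects: int = 7
    n_mouse_subjects: int = 5
    donor_sd_human: float = 1.0
    donor_sd_mouse: float = 0.2
    time_effect_sd: float = 1.0
    nutrient_effect_size: float = 0.5
    frac_null: float = 0.8
    frac_time: float = 0.1
    frac_shared_nutrient: float = 0.05
    frac_divergent_nutrient: float = 0.05
    nb_dispersion: float = 0.1
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.3
    outlier_samples: int = 0
    outlier_shift_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.frac_null,
            self.frac_time,
            self.frac_shared_nutrient,
            self.frac_divergent_nutrient,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("gene-class fractions must lie in [0, 1]")
        if not math.isclose(sum(fracs), 1.0, abs_tol=1e-9):
            raise ValueError(f"gene-class fractions must sum to 1, got {sum(fracs)}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if min(self.n_human_subjects, self.n_mouse_subjects) < 2:
            raise ValueError("need at least 2 subjects per species")
        for name in ("donor_sd_human", "donor_sd_mouse", "time_effect_sd",
                     "nb_dispersion", "lib_size_cv", "outlier_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        if self.outlier_samples < 0:
            raise ValueError("outlier_samples must be non-negative")

    def subjects(self, species: str) -> list[str]:
        """Subject ids; the study's own ids when the count matches the study."""
        if species == "human":
            if self.n_human_subjects == len(HUMAN_DONORS):
                return list(HUMAN_DONORS)
            return [f"H{i + 1:02d}" for i in range(self.n_human_subjects)]
        if self.n_mouse_subjects == len(MOUSE_SUBJECTS):
            return list(MOUSE_SUBJECTS)
        return [f"M{i + 1:02d}" for i in range(self.n_mouse_subjects)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthLedger:
    """Ground truth of a simulated study.

    ``genes`` has one row per ortholog pair: gene ids in both species, class
    label, per-species nutrient effect sign (0 for non-nutrient classes;
    opposite across species for the divergent class), the time effect (log2,
    applied at 48 h in every medium) and the baseline log2 abundance.
    ``outliers`` maps species -> list of sample ids that carry an injected
    gene-wise shift.
    """

    genes: pd.DataFrame
    outliers: dict[str, list[str]] = field(default_factory=dict)
    nutrient_effect_size: float = 1.0

    def gene_ids(self, species: str) -> pd.Index:
        return pd.Index(self.genes[f"gene_{species[0]}"])

    def true_log2fc(self, species: str, contrast: ContrastSpec) -> pd.Series:
        """Planted log2 fold change of a medium-vs-time-matched-CTR contrast.

        Time-class effects cancel in time-matched contrasts; only nutrient
        classes respond, scaled by the medium's dose score.
        """
        sign = self.genes[f"sign_{species[0]}"].to_numpy(dtype=float)
        fc = sign * self.nutrient_effect_size * dose_score(contrast.test_medium)
        return pd.Series(fc, index=self.gene_ids(species), name=contrast.contrast_id)

    def classes(self, species: str | None = None) -> pd.Series:
        idx = self.gene_ids(species) if species else self.genes.index
        return pd.Series(self.genes["gene_class"].to_numpy(), index=idx)


@dataclass
class SimulatedStudy:
    """Both species arms of one simulated experiment sharing one truth ledger."""

    counts: dict[str, pd.DataFrame]
    metadata: dict[str, pd.DataFrame]
    truth: TruthLedger
    config: SimulationConfig


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    probs = [
        config.frac_null,
        config.frac_time,
        config.frac_shared_nutrient,
        config.frac_divergent_nutrient,
    ]
    classes = rng.choice(GENE_CLASSES, size=n, p=probs)
    base = rng.normal(3.0, 2.0, size=n)  # relative log2 abundance
    time_eff = np.where(classes == "time", rng.normal(0.0, config.time_effect_sd, n), 0.0)
    sign_h = np.where(
        np.isin(classes, ("shared_nutrient", "divergent_nutrient")),
        rng.choice([-1, 1], size=n),
        0,
    )
    sign_m = np.where(classes == "divergent_nutrient", -sign_h, sign_h)
    return pd.DataFrame(
        {
            "gene_h": [f"HG{i:06d}" for i in range(n)],
            "gene_m": [f"MG{i:06d}" for i in range(n)],
            "gene_class": classes,
            "sign_h": sign_h,
            "sign_m": sign_m,
            "time_effect": time_eff,
            "base_log2": base,
        }
    )


def _metadata_frame(design) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "species": d.species,
                "subject_id": d.subject_id,
                "medium": d.medium,
                "timepoint_h": d.timepoint_h,
                "status": d.status,
            }
            for d in design
        ]
    )


def _simulate_arm(
    config: SimulationConfig,
    species: str,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    subjects = config.subjects(species)
    design = enumerate_design(species, subjects)
    meta = _metadata_frame(design)
    n_genes, n_samples = config.n_genes, len(design)

    donor_sd = config.donor_sd_human if species == "human" else config.donor_sd_mouse
    subj_eff = rng.normal(0.0, donor_sd, size=(n_genes, len(subjects)))
    subj_idx = {s: j for j, s in enumerate(subjects)}

    sign = truth[f"sign_{species[0]}"].to_numpy(dtype=float)
    time_eff = truth["time_effect"].to_numpy()
    base = truth["base_log2"].to_numpy()
    doses = np.array([dose_score(m) for m in MEDIUM_ORDER])
    dose_of = dict(zip(MEDIUM_ORDER, doses))

    log2_mu = np.empty((n_genes, n_samples))
    for s, d in enumerate(design):
        x = base + subj_eff[:, subj_idx[d.subject_id]]
        if d.timepoint_h == 48:
            x = x + time_eff
        x = x + sign * config.nutrient_effect_size * dose_of[d.medium]
        log2_mu[:, s] = x

    outlier_ids: list[str] = []
    if config.outlier_samples > 0:
        k = min(config.outlier_samples, n_samples)
        picks = rng.choice(n_samples, size=k, replace=False)
        for s in picks:
            log2_mu[:, s] += rng.normal(0.0, config.outlier_shift_sd, size=n_genes)
        outlier_ids = [design[s].sample_id for s in sorted(picks)]

    # log-normal library sizes with the requested mean and CV
    sigma2 = math.log1p(config.lib_size_cv**2)
    lib_sizes = rng.lognormal(
        math.log(config.lib_size_mean) - sigma2 / 2.0, math.sqrt(sigma2), size=n_samples
    )

    w = np.exp2(log2_mu)
    mu = lib_sizes * w / w.sum(axis=0, keepdims=True)
    phi = config.nb_dispersion
    if phi > 0:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    gene_ids = truth[f"gene_{species[0]}"].to_numpy()
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=meta["sample_id"].to_numpy())
    return counts_df, meta, outlier_ids


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate both species arms from one seed with a shared truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _draw_truth(config, rng)
    truth = TruthLedger(genes=genes, nutrient_effect_size=config.nutrient_effect_size)
    counts: dict[str, pd.DataFrame] = {}
    metadata: dict[str, pd.DataFrame] = {}
    for species in ("human", "mouse"):
        c, m, out = _simulate_arm(config, species, genes, rng)
        counts[species] = c
        metadata[species] = m
        truth.outliers[species] = out
    return SimulatedStudy(counts=counts, metadata=metadata, truth=truth, config=config)


def simulate_experiment(
    config: SimulationConfig, species: str = "human"
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Simulate a single species arm: ``(counts, metadata, truth)``.

    The truth ledger is drawn from the same seed as in :func:`simulate_study`,
    so the two entry points plant identical gene classes and effects.
    """
    if species not in ("human", "mouse"):
        raise ValueError(f"unknown species {species!r}")
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _draw_truth(config, rng)
    truth = TruthLedger(genes=genes, nutrient_effect_size=config.nutrient_effect_size)
    if species == "mouse":
        # burn the human arm's stream so each arm sees the draws it would see
        # inside simulate_study
        _simulate_arm(config, "human", genes, rng)
    c, m, out = _simulate_arm(config, species, genes, rng)
    truth.outliers[species] = out
    return c, m, truth


def simulate_ortholog_map(
    n_genes: int,
    identity_mean: float = 85.0,
    identity_sd: float = 8.0,
    seed: int = 0,
    truth: TruthLedger | None = None,
    coupling: float = 0.0,
) -> pd.DataFrame:
    """One-to-one human-mouse ortholog map with % global sequence identity.

    Identities are normal(identity_mean, identity_sd) clipped to [0, 100].
    With ``coupling`` in (0, 1] and a truth ledger, identity is positively
    coupled to planted cross-species concordance (shared-effect genes drawn
    toward higher identity, divergent genes toward lower), which lets
    correlation-vs-identity analyses be tested against a known monotone
    association.
    """
    if truth is not None and len(truth.genes) != n_genes:
        raise ValueError(
            f"ortholog map size {n_genes} does not match simulated study "
            f"({len(truth.genes)} genes)"
        )
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    eps = rng.normal(size=n_genes)
    if coupling > 0.0:
        if truth is None:
            raise ValueError("coupling requires a truth ledger")
        concord = np.select(
            [
                truth.genes["gene_class"] == "shared_nutrient",
                truth.genes["gene_class"] == "divergent_nutrient",
            ],
            [1.0, -1.0],
            default=0.0,
        )
        z = coupling * concord + math.sqrt(1.0 - coupling**2) * eps
    else:
        z = eps
    identity = np.clip(identity_mean + identity_sd * z, 0.0, 100.0)
    if truth is not None:
        gene_h = truth.genes["gene_h"].to_numpy()
        gene_m = truth.genes["gene_m"].to_numpy()
    else:
        gene_h = [f"HG{i:06d}" for i in range(n_genes)]
        gene_m = [f"MG{i:06d}" for i in range(n_genes)]
    return pd.DataFrame({"gene_h": gene_h, "gene_m": gene_m, "pct_identity": identity})
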