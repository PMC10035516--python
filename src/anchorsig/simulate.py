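"""Synthetic bulk-expression cohorts with planted signature structure.

The generator emulates the statistical structure the analysis assumes: a
small cohort (default 38 samples, 6 of them intra-patient lesion pairs)
with a latent mesenchymal factor per sample; one anchor transcription
factor loading strongly on the factor; a block of co-expressed signature
genes with uniform loadings; immune-checkpoint markers correlated with the
latent factor at stated strengths; decoy transcription factors and
independent background genes. A planted "high" subgroup of samples
(default 16% of the cohort, assigned at patient level so lesion pairs never
split) has its latent factor shifted upward. Ground truth for every sample
and gene is returned alongside the matrix.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, GeneSet, write_expression_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortConfig",
    "CohortTruth",
    "generate_cohort",
    "write_cohort",
    "synthetic_emt_overlap_sets",
]

#: Decoy EMT transcription factors: unit noise, no loading on the factor.
DECOY_TFS: tuple[str, ...] = ("ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TWIST2")

#: Intra-pair share of latent variance (multi-lesion patients).
_PATIENT_VARIANCE_SHARE = 0.9

#: Expression values are clipped to this positive log2 intensity range.
_LOG2_RANGE = (2.0, 18.0)


def _default_checkpoint_correlations() -> dict[str, float]:
    return {"HAVCR2": 0.83, "VISTA": 0.58, "CTLA4": 0.55, "TIGIT": 0.54, "CD163": 0.86}


@dataclass
class SyntheticCohortConfig:
    """Generative parameters for a synthetic cohort.

    Defaults mirror the study conditions of the discovery cohort: 38
    samples with 6 lesion pairs, a 16% planted high-expression subgroup, a
    400-gene signature block with loadings in [0.5, 1.0] on the latent
    factor, an anchor shift/loading of 2.5 log2 units, unit Gaussian noise
    on the log2 scale, and checkpoint markers at the stated target
    correlations with the latent factor.
    """

    n_samples: int = 38
    n_patient_pairs: int = 6
    high_fraction: float = 0.16
    n_signature_genes: int = 400
    n_background_genes: int = 5000
    anchor_effect: float = 2.5
    signature_loading_range: tuple[float, float] = (0.5, 1.0)
    checkpoint_correlations: dict[str, float] = field(
        default_factory=_default_checkpoint_correlations
    )
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    anchor_name: str = "PRRX1"
    noise_dist: str = "gaussian"  # or "student_t" (df=4, heavier tails)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.high_fraction < 1:
            raise ValueError("high_fraction must be in (0, 1)")
        if self.n_patient_pairs * 2 > self.n_samples:
            raise ValueError("n_patient_pairs * 2 must not exceed n_samples")
        for marker, rho in self.checkpoint_correlations.items():
            if not -1 < rho < 1:
                raise ValueError(f"target correlation for {marker} must be in (-1, 1)")
        if self.noise_dist not in ("gaussian", "student_t"):
            raise ValueError("noise_dist must be 'gaussian' or 'student_t'")


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort."""

    latent: pd.Series  # per-sample mesenchymal factor
    high_samples: list[str]  # planted high-subgroup members
    signature_genes: list[str]  # planted co-expressed block
    loadings: pd.Series  # gene -> loading on the latent factor
    marker_targets: dict[str, float]  # marker -> target correlation
    patient_pairs: list[tuple[str, str]]  # sample-id pairs sharing a patient

    @property
    def subgroup_indicator(self) -> pd.Series:
        ind = pd.Series("background", index=self.latent.index, name="planted_subgroup")
        ind[self.high_samples] = "high"
        return ind


def _noise(rng: np.random.Generator, size, sd: float, dist: str) -> np.ndarray:
    if dist == "student_t":
        df = 4
        # scale so the marginal sd equals sd
        return rng.standard_t(df, size=size) * sd / math.sqrt(df / (df - 2))
    return rng.normal(0.0, sd, size=size)


def generate_cohort(config: SyntheticCohortConfig) -> tuple[ExpressionMatrix, CohortTruth]:
    """Generate one synthetic cohort plus its ground truth.

    The latent factor is standard normal across samples (split into a
    patient-level effect and a lesion-level residual so intra-pair
    correlation is 0.9) and shifted by ``anchor_effect`` for planted-high
    samples. The anchor gene is ``baseline + anchor_effect * m + noise``;
    each signature gene is ``baseline_i + lambda_i * m + noise`` with
    lambda_i uniform in the loading range; each checkpoint marker is built
    as ``rho * standardized(m) + sqrt(1 - rho^2) * z`` rescaled to
    expression units so its population correlation with the factor is the
    target; background genes are independent noise. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_pairs = config.n_patient_pairs

    # --- patients and samples -------------------------------------------
    n_patients = n - n_pairs
    patients = [f"P{i + 1:03d}" for i in range(n_patients)]
    sample_patient: list[str] = []
    for p in patients[:n_pairs]:
        sample_patient += [p, p]
    sample_patient += patients[n_pairs:]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    patient_of = pd.Series(sample_patient, index=sample_ids, name="patient_id")
    pairs = [
        (sample_ids[2 * i], sample_ids[2 * i + 1]) for i in range(n_pairs)
    ]

    # --- planted high subgroup (patient level, pairs never split) --------
    target_high = int(round(config.high_fraction * n))
    n_samples_of = {p: sample_patient.count(p) for p in patients}
    shuffled = list(patients)
    rng.shuffle(shuffled)
    high_patients: set[str] = set()
    budget = target_high
    for p in shuffled:
        if n_samples_of[p] <= budget:
            high_patients.add(p)
            budget -= n_samples_of[p]
        if budget == 0:
            break
    if budget:
        logger.warning("planted high subgroup has %d samples, target %d",
                       target_high - budget, target_high)
    high_samples = [s for s in sample_ids if patient_of[s] in high_patients]

    # --- latent mesenchymal factor --------------------------------------
    patient_effect = rng.normal(0.0, math.sqrt(_PATIENT_VARIANCE_SHARE), n_patients)
    effect_of = dict(zip(patients, patient_effect))
    residual = rng.normal(0.0, math.sqrt(1 - _PATIENT_VARIANCE_SHARE), n)
    m = np.array([effect_of[p] for p in sample_patient]) + residual
    m[[sample_ids.index(s) for s in high_samples]] += config.anchor_effect
    latent = pd.Series(m, index=sample_ids, name="latent_factor")

    # --- genes -----------------------------------------------------------
    sig_genes = [f"SIG{i + 1:04d}" for i in range(config.n_signature_genes)]
    bg_genes = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    markers = list(config.checkpoint_correlations)
    lo, hi = config.signature_loading_range
    lam = rng.uniform(lo, hi, config.n_signature_genes)

    blocks: list[np.ndarray] = []
    gene_order: list[str] = []
    loadings: dict[str, float] = {}

    anchor_row = (
        config.baseline_mean
        + config.anchor_effect * m
        + _noise(rng, n, config.noise_sd, config.noise_dist)
    )
    blocks.append(anchor_row[None, :])
    gene_order.append(config.anchor_name)
    loadings[config.anchor_name] = config.anchor_effect

    decoy_rows = config.baseline_mean + _noise(
        rng, (len(DECOY_TFS), n), 1.0, config.noise_dist
    )
    blocks.append(decoy_rows)
    gene_order += list(DECOY_TFS)
    loadings.update({tf: 0.0 for tf in DECOY_TFS})

    sig_baselines = rng.normal(config.baseline_mean, 1.0, config.n_signature_genes)
    sig_rows = (
        sig_baselines[:, None]
        + lam[:, None] * m[None, :]
        + _noise(rng, (config.n_signature_genes, n), config.noise_sd, config.noise_dist)
    )
    blocks.append(sig_rows)
    gene_order += sig_genes
    loadings.update(dict(zip(sig_genes, lam.astype(float))))

    m_std = (m - m.mean()) / m.std() if m.std() > 0 else np.zeros(n)
    for marker, rho in config.checkpoint_correlations.items():
        z = rng.normal(0.0, 1.0, n)
        x = rho * m_std + math.sqrt(1 - rho**2) * z
        blocks.append((config.baseline_mean + config.noise_sd * x)[None, :])
        gene_order.append(marker)
        loadings[marker] = rho

    bg_baselines = rng.normal(config.baseline_mean, 1.0, config.n_background_genes)
    bg_rows = bg_baselines[:, None] + _noise(
        rng, (config.n_background_genes, n), config.noise_sd, config.noise_dist
    )
    blocks.append(bg_rows)
    gene_order += bg_genes
    loadings.update({g: 0.0 for g in bg_genes})

    values = pd.DataFrame(
        np.clip(np.vstack(blocks), *_LOG2_RANGE),
        index=pd.Index(gene_order, name="gene"),
        columns=sample_ids,
    )

    # --- metadata: sex mirrors the study's high-subgroup skew -----------
    women = set(high_patients)
    target_women = max(int(round(0.42 * n_patients)), len(women))
    others = [p for p in patients if p not in women]
    rng.shuffle(others)
    women |= set(others[: target_women - len(women)])
    metadata = pd.DataFrame(
        {
            "sex": ["F" if patient_of[s] in women else "M" for s in sample_ids],
            "primary_side": rng.choice(["right", "left"], size=n, p=[0.26, 0.74]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    matrix = ExpressionMatrix(values=values, patient_ids=patient_of, metadata=metadata)
    truth = CohortTruth(
        latent=latent,
        high_samples=high_samples,
        signature_genes=sig_genes,
        loadings=pd.Series(loadings, name="loading"),
        marker_targets=dict(config.checkpoint_correlations),
        patient_pairs=pairs,
    )
    return matrix, truth


def write_cohort(
    matrix: ExpressionMatrix, truth: CohortTruth, directory: str | Path, stem: str = "cohort"
) -> None:
    """Write the cohort TSV (expression_io dialect) plus a truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(matrix, directory / f"{stem}.tsv")
    payload = {
        "latent": truth.latent.to_dict(),
        "high_samples": truth.high_samples,
        "signature_genes": truth.signature_genes,
        "loadings": truth.loadings.to_dict(),
        "marker_targets": truth.marker_targets,
        "patient_pairs": truth.patient_pairs,
    }
    (directory / f"{stem}.truth.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Synthetic EMT gene-set quartet for overlap analyses
# ---------------------------------------------------------------------------

#: Genes shared by the cohort signature and all three public EMT sets.
CORE_OVERLAP_GENES: tuple[str, ...] = (
    "CDH11", "DCN", "EMP3", "FBN1", "FSTL1", "LOX",
    "MMP2", "PMP22", "SPOCK1", "TAGLN", "VCAN", "VIM",
)

#: Genes shared by the three public EMT sets but absent from the signature.
PUBLIC_ONLY_OVERLAP_GENES: tuple[str, ...] = ("CDH2", "FBLN1", "FN1", "MYL9", "PTX3")


def synthetic_emt_overlap_sets() -> list[GeneSet]:
    """Synthetic stand-ins for the four EMT/mesenchymal gene sets.

    The full public gene lists are not bundled, so these sets are built
    synthetically: they have the published sizes (405 cohort signature, 200
    Hallmark-EMT-like, 170 tumor-MES-like, 131 EMT-core-like) and the
    published shared-membership structure — a 12-gene core common to all
    four, 5 genes common to the three public sets but absent from the
    signature, and the anchor present in the signature and the
    Hallmark-like set only. All remaining members are set-unique filler
    symbols.
    """
    sizes = {
        "signature_synthetic": 405,
        "hallmark_emt_synthetic": 200,
        "tumor_mes_synthetic": 170,
        "emt_core_synthetic": 131,
    }
    core = set(CORE_OVERLAP_GENES)
    public_only = set(PUBLIC_ONLY_OVERLAP_GENES)
    membership = {
        "signature_synthetic": core | {"PRRX1"},
        "hallmark_emt_synthetic": core | public_only | {"PRRX1"},
        "tumor_mes_synthetic": core | public_only,
        "emt_core_synthetic": core | public_only,
    }
    sets = []
    for name, size in sizes.items():
        genes = set(membership[name])
        fill = size - len(genes)
        genes |= {f"{name.upper()}_FILL{i + 1:04d}" for i in range(fill)}
        sets.append(GeneSet(name=name, genes=frozenset(genes), source="synthetic stand-in"))
    return sets
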