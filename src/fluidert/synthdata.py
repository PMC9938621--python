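"""Synthetic uterine-fluid RNA-seq cohorts with planted receptivity structure.

The training cohort emulates the study design behind the receptivity test:
48 patients each sampled at three stage-timed points (pre-receptive LH+5,
receptive LH+7, post-receptive LH+9), ~15k expressed genes, a planted set of
stage-associated genes, and a handful of correlated co-expression modules
each carrying one high-connectivity hub gene.  The validation cohort is a
set of single-timepoint transfer-day samples with hidden true stages and
binary pregnancy outcomes.

On the log2 scale each value decomposes additively into a gene baseline, a
gene-specific stage effect, an (optional) cycle-protocol effect, a module
latent-factor contribution and Gaussian residual noise.  Counts, when
requested, are negative-binomial draws whose means invert the FPKM
transform, so the normalisation path recovers the latent matrix up to noise.

Every draw flows from one :class:`numpy.random.Generator` seeded from the
config, so identical configs produce byte-identical serialised output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exprio import ExpressionDataset

STAGES = ("PR", "RE", "PO")
STAGE_DAYS = {"PR": "LH+5", "RE": "LH+7", "PO": "LH+9"}


class ConfigError(ValueError):
    """A simulation config field is out of range or inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Standard deviations are on the log2 expression scale.  Defaults mirror
    the study design: 48 training patients x 3 stages, 864 planted
    stage-associated genes among 15,000, four co-expression modules with one
    planted hub each, and a 22-sample single-timepoint validation cohort in
    which pregnancy is likely only when the endometrium is truly receptive.
    """

    n_patients: int = 48
    samples_per_patient: int = 3  # fixed: PR/RE/PO at LH+5/7/9
    n_genes: int = 15000
    n_deg: int = 864
    stage_effect_sd: float = 0.8
    treatment_effect_sd: float = 0.0  # training cycles are all natural
    residual_sd: float = 0.35
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (60, 50, 40, 30)
    module_factor_sd: float = 2.5
    module_stage_corr: float = 0.8  # stage-linked share of each module factor
    hub_loading_boost: float = 1.5
    nb_dispersion: float = 0.05
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_mean: float = 5_000_000.0
    validation_n: int = 22
    validation_stage_probs: tuple[float, float, float] = (0.14, 0.81, 0.05)
    p_preg_receptive: float = 0.78
    p_preg_displaced: float = 0.0
    validation_qc_fail: int = 1
    emit_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.samples_per_patient != 3:
            raise ConfigError("samples_per_patient is fixed at 3 (PR/RE/PO)")
        if not (0 <= self.n_deg <= self.n_genes):
            raise ConfigError("n_deg must satisfy 0 <= n_deg <= n_genes")
        if self.n_modules != len(self.module_sizes):
            raise ConfigError("n_modules must equal len(module_sizes)")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("sum(module_sizes) must be <= n_genes")
        if self.module_sizes and sum(self.module_sizes) > max(self.n_deg, 0) and self.n_deg > 0:
            raise ConfigError("module genes are drawn from the planted DEG set; "
                              "sum(module_sizes) must be <= n_deg")
        for name in ("stage_effect_sd", "treatment_effect_sd", "residual_sd",
                     "baseline_log_sd", "module_factor_sd", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 <= self.module_stage_corr <= 1):
            raise ConfigError("module_stage_corr must be in [0, 1]")
        if self.hub_loading_boost < 1:
            raise ConfigError("hub_loading_boost must be >= 1")
        if self.gene_length_range[0] <= 0 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ConfigError("gene_length_range must be a positive interval")
        if abs(sum(self.validation_stage_probs) - 1.0) > 1e-9:
            raise ConfigError("validation_stage_probs must sum to 1")
        for name in ("p_preg_receptive", "p_preg_displaced"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must be a probability")
        if not (0 <= self.validation_qc_fail <= self.validation_n):
            raise ConfigError("validation_qc_fail must be <= validation_n")


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted, for recovery tests."""

    deg_gene_ids: list[str]
    stage_offsets: pd.DataFrame  # genes x (PR, RE, PO); zero rows for non-DEGs
    module_membership: dict[str, str]  # gene -> module name ("M1"...)
    hub_genes: dict[str, str]  # module name -> hub gene id
    validation_true_stages: dict[str, str] = field(default_factory=dict)
    validation_outcomes: dict[str, str] = field(default_factory=dict)
    validation_qc_fail: list[str] = field(default_factory=list)
    # private generator state needed to emit a consistent validation cohort
    params: dict = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "deg_gene_ids": self.deg_gene_ids,
            "stage_offsets": {g: [float(x) for x in row]
                              for g, row in self.stage_offsets.iterrows()
                              if np.any(np.asarray(row) != 0)},
            "module_membership": self.module_membership,
            "hub_genes": self.hub_genes,
            "validation_true_stages": self.validation_true_stages,
            "validation_outcomes": self.validation_outcomes,
            "validation_qc_fail": self.validation_qc_fail,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# three centred stage patterns spanning the contrast space; modules cycle
# through them with alternating sign so module-stage correlations vary.
def _stage_patterns(n_modules: int) -> np.ndarray:
    linear = np.array([-1.0, 0.0, 1.0]) * math.sqrt(3.0 / 2.0)
    quad = np.array([1.0, -2.0, 1.0]) / math.sqrt(2.0)
    base = [linear, quad, -linear, -quad]
    return np.array([base[m % 4] for m in range(n_modules)])


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _plant_genome(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw the per-gene parameters shared by training and validation."""
    g = config.n_genes
    genes = _gene_ids(g)
    mu = np.clip(rng.normal(config.baseline_log_mean, config.baseline_log_sd, g), 0.05, None)
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, g).astype(float)

    deg_idx = np.sort(rng.choice(g, size=config.n_deg, replace=False))
    # stage offsets: iid per stage, centred per gene
    delta = np.zeros((g, 3))
    delta[deg_idx] = rng.normal(0.0, config.stage_effect_sd, (config.n_deg, 3))
    delta[deg_idx] -= delta[deg_idx].mean(axis=1, keepdims=True)

    # modules occupy the head of a shuffled copy of the DEG list
    module_pool = rng.permutation(deg_idx)
    patterns = _stage_patterns(config.n_modules)
    loadings = np.zeros(g)
    module_of = np.full(g, -1)
    hubs = {}
    pos = 0
    for m, size in enumerate(config.module_sizes):
        members = module_pool[pos:pos + size]
        pos += size
        lam = rng.uniform(0.9, 1.0, size) * config.module_factor_sd
        hub_local = int(rng.integers(size))
        lam[hub_local] = config.hub_loading_boost * config.module_factor_sd
        loadings[members] = lam
        module_of[members] = m
        hubs[f"M{m + 1}"] = genes[members[hub_local]]
        # module members' stage effect is mediated entirely by the factor
        alpha = config.module_stage_corr
        delta[members] = lam[:, None] * alpha * patterns[m][None, :]
        # module genes are high-expressed so the planted swings are rarely
        # truncated by the log2(FPKM+1) floor at zero
        noise_sd = lam * math.sqrt(max(0.0, 1.0 - alpha ** 2))
        floor = -delta[members].min(axis=1) + 2.0 * noise_sd
        mu[members] = np.maximum(mu[members], floor + 0.5)

    protocol_effect = rng.normal(0.0, config.treatment_effect_sd, g)

    return {
        "genes": genes, "mu": mu, "lengths": lengths, "delta": delta,
        "deg_idx": deg_idx, "loadings": loadings, "module_of": module_of,
        "patterns": patterns, "hubs": hubs, "protocol_effect": protocol_effect,
    }


def _emit_samples(config: SimulationConfig, params: dict, rng: np.random.Generator,
                  stages: list[str], protocols: list[str]) -> np.ndarray:
    """Latent log2(FPKM+1) matrix for samples with the given stage labels."""
    g, n = config.n_genes, len(stages)
    stage_idx = np.array([STAGES.index(s) for s in stages])
    y = params["mu"][:, None] + params["delta"][:, stage_idx]
    if config.treatment_effect_sd > 0:
        is_hrt = np.array([p == "HRT" for p in protocols], dtype=float)
        y = y + params["protocol_effect"][:, None] * is_hrt[None, :]
    alpha = config.module_stage_corr
    noise_scale = math.sqrt(max(0.0, 1.0 - alpha ** 2))
    for m in range(config.n_modules):
        members = np.where(params["module_of"] == m)[0]
        if not len(members):
            continue
        eta = rng.normal(0.0, 1.0, n) * noise_scale
        y[members] += params["loadings"][members][:, None] * eta[None, :]
    y = y + rng.normal(0.0, config.residual_sd, (g, n))
    return np.clip(y, 0.0, None)


def _latent_to_counts(config: SimulationConfig, params: dict,
                      rng: np.random.Generator, latent: np.ndarray) -> np.ndarray:
    """NB counts whose means invert log2(FPKM+1) at the drawn library sizes."""
    fpkm_true = np.power(2.0, latent) - 1.0
    lib = config.library_size_mean * rng.uniform(0.8, 1.2, latent.shape[1])
    mean = fpkm_true * params["lengths"][:, None] * lib[None, :] / 1e9
    phi = config.nb_dispersion
    if phi <= 0:
        return rng.poisson(mean).astype(np.int64)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def _degrade_library(rng: np.random.Generator, column: np.ndarray,
                     keep_fraction: float = 0.03) -> np.ndarray:
    """Emulate a failed library: almost all genes drop out."""
    keep = rng.random(column.shape[0]) < keep_fraction
    return np.where(keep, column, 0)


def simulate_training_cohort(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate the stage-timed training cohort plus its truth ledger.

    Returns a dataset on the ``log2`` scale (or ``counts`` when
    ``config.emit_counts``) with 3 x ``n_patients`` samples, and a
    :class:`GroundTruth` recording planted DEGs, their stage offsets, module
    membership and the planted hub of every module.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    params = _plant_genome(config, rng)

    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]
    sample_ids, stages, meta_rows = [], [], []
    for p in patients:
        for s in STAGES:
            sample_ids.append(f"{p}_{s}")
            stages.append(s)
            meta_rows.append((f"{p}_{s}", p, STAGE_DAYS[s], s, "natural", "unknown"))
    protocols = ["natural"] * len(sample_ids)

    latent = _emit_samples(config, params, rng, stages, protocols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "patient_id", "day",
                                            "stage", "protocol", "outcome"]).set_index("sample_id")
    lengths = pd.Series(params["lengths"], index=params["genes"], name="length_bp")

    if config.emit_counts:
        counts = _latent_to_counts(config, params, rng, latent)
        values = pd.DataFrame(counts, index=params["genes"], columns=sample_ids)
        dataset = ExpressionDataset(values, meta, "counts", lengths)
    else:
        values = pd.DataFrame(latent, index=params["genes"], columns=sample_ids)
        dataset = ExpressionDataset(values, meta, "log2", lengths)

    genes = params["genes"]
    truth = GroundTruth(
        deg_gene_ids=[genes[i] for i in params["deg_idx"]],
        stage_offsets=pd.DataFrame(params["delta"], index=genes, columns=list(STAGES)),
        module_membership={genes[i]: f"M{params['module_of'][i] + 1}"
                           for i in np.where(params["module_of"] >= 0)[0]},
        hub_genes=dict(params["hubs"]),
        params={"config_seed": config.seed, **params},
    )
    return dataset, truth


def simulate_validation_cohort(config: SimulationConfig,
                               truth: GroundTruth) -> ExpressionDataset:
    """Generate transfer-day samples with hidden stages and outcomes.

    True stage per sample is drawn from ``validation_stage_probs``; pregnancy
    is Bernoulli with ``p_preg_receptive`` when the endometrium is truly
    receptive and ``p_preg_displaced`` otherwise.  ``validation_qc_fail``
    libraries are degraded to exercise the detection-failure path; their ids
    are recorded in the truth ledger.  Hidden stages and outcomes are written
    into ``truth``; the returned metadata carries ``stage = unknown``.
    """
    config.validate()
    params = truth.params
    if not params or list(params["genes"]) != _gene_ids(config.n_genes):
        raise ConfigError("gene universe mismatch between config and training truth")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77_000_001]))

    n = config.validation_n
    sample_ids = [f"V{i:03d}" for i in range(1, n + 1)]
    true_stages = [STAGES[i] for i in rng.choice(3, size=n, p=config.validation_stage_probs)]
    protocols = ["HRT" if rng.random() < 0.64 else "natural" for _ in range(n)]
    outcomes = []
    for s in true_stages:
        p = config.p_preg_receptive if s == "RE" else config.p_preg_displaced
        outcomes.append("pregnant" if rng.random() < p else "not_pregnant")

    latent = _emit_samples(config, params, rng, true_stages, protocols)
    fail_ids = []
    if config.validation_qc_fail:
        fail_pos = rng.choice(n, size=config.validation_qc_fail, replace=False)
        fail_ids = [sample_ids[i] for i in sorted(fail_pos)]

    meta = pd.DataFrame({
        "patient_id": sample_ids,
        "day": ["transfer"] * n,
        "stage": ["unknown"] * n,
        "protocol": protocols,
        "outcome": outcomes,
    }, index=pd.Index(sample_ids, name="sample_id"))
    lengths = pd.Series(params["lengths"], index=params["genes"], name="length_bp")

    if config.emit_counts:
        counts = _latent_to_counts(config, params, rng, latent)
        for s in fail_ids:
            j = sample_ids.index(s)
            counts[:, j] = _degrade_library(rng, counts[:, j])
        values = pd.DataFrame(counts, index=params["genes"], columns=sample_ids)
        dataset = ExpressionDataset(values, meta, "counts", lengths)
    else:
        for s in fail_ids:
            j = sample_ids.index(s)
            latent[:, j] = _degrade_library(rng, latent[:, j])
        values = pd.DataFrame(latent, index=params["genes"], columns=sample_ids)
        dataset = ExpressionDataset(values, meta, "log2", lengths)

    truth.validation_true_stages = dict(zip(sample_ids, true_stages))
    truth.validation_outcomes = dict(zip(sample_ids, outcomes))
    truth.validation_qc_fail = fail_ids
    return dataset
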