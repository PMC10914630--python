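"""Synthetic postmortem proteomics cohorts with recorded ground truth.

The generator emulates the statistical structure of a two-group (unaffected
vs OUD) TMT proteomics study: per-protein log2 intensities composed of a
mesor, an optional 24-h sinusoid anchored to each subject's Zeitgeber time
of death, a group effect (differential expression), demographic covariate
slopes, a per-plex batch offset, correlated co-expression modules built from
shared latent factors, and Gaussian residual noise.  A paired
homogenate/synaptosome variant adds a per-protein synaptic enrichment fold.

Every planted signal is recorded in a :class:`GroundTruth` object so that
recovery by the analysis stages can be measured exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, ExpressionMatrix, SubjectRecord
from .rhythm import tod_to_zt

_STREAM_COHORT = 101
_STREAM_PAIRED = 102


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study design being emulated: 20 subjects per
    group (matched pairs), ~2000 quantified proteins, a modest fraction of
    diurnally rhythmic and differentially expressed proteins, TMT 10-plex
    batches, and log2-scale residual noise typical of isobaric-label
    protein quantification.
    """

    n_per_group: int = 20
    n_proteins: int = 2000
    frac_rhythmic: float = 0.05
    amplitude_range: tuple = (0.2, 0.8)          # log2 units
    frac_de: float = 0.02
    de_logfc_range: tuple = (0.3, 0.8)           # |log2FC|, sign random
    frac_enriched: float = 0.25
    enrich_fold_range: tuple = (1.5, 3.0)        # linear fold, synaptosome/homogenate
    n_modules: int = 5
    module_size: int = 50
    module_cor_by_group: dict = field(
        default_factory=lambda: {"unaffected": 0.6, "OUD": 0.6}
    )
    rhythm_loss_frac: float = 0.3
    rhythm_gain_frac: float = 0.0
    noise_sd: float = 0.3                        # log2 units
    plex_sd: float = 0.1                         # log2 units
    covariate_effects: dict = field(default_factory=dict)  # e.g. {"age": 0.005}
    tod_sampling: str = "uniform"                # or "empirical-like"
    region: str = "NAc"
    preparation: str = "synaptosome"
    sunrise: float = 6.0
    sunset: float = 18.0
    mesor_mean: float = 10.0
    mesor_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_rhythmic", "frac_de", "frac_enriched",
                     "rhythm_loss_frac", "rhythm_gain_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_per_group <= 0 or self.n_proteins <= 0:
            raise ValueError("counts must be positive")
        for name in ("amplitude_range", "de_logfc_range", "enrich_fold_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} low {lo} exceeds high {hi}")
        if self.tod_sampling not in ("uniform", "empirical-like"):
            raise ValueError(f"unknown tod_sampling {self.tod_sampling!r}")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError(
                f"module_size x n_modules = {self.n_modules * self.module_size} "
                f"exceeds n_proteins = {self.n_proteins}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["amplitude_range"] = list(d["amplitude_range"])
        d["de_logfc_range"] = list(d["de_logfc_range"])
        d["enrich_fold_range"] = list(d["enrich_fold_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for name in ("amplitude_range", "de_logfc_range", "enrich_fold_range"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted per-protein and per-sample signals of a simulated cohort."""

    proteins: pd.DataFrame   # one row per protein
    samples: pd.DataFrame    # one row per sample
    config: SimulationConfig

    @property
    def rhythmic_unaffected(self) -> set:
        p = self.proteins
        return set(p.loc[p["rhythmic_unaffected"], "protein_id"])

    @property
    def rhythmic_oud(self) -> set:
        p = self.proteins
        return set(p.loc[p["rhythmic_oud"], "protein_id"])

    @property
    def de_proteins(self) -> set:
        p = self.proteins
        return set(p.loc[p["true_logfc"] != 0.0, "protein_id"])

    @property
    def enriched_proteins(self) -> set:
        p = self.proteins
        return set(p.loc[p["enriched"], "protein_id"])


def _sample_tod(rng: np.random.Generator, n: int, mode: str) -> np.ndarray:
    if mode == "uniform":
        return rng.uniform(0.0, 24.0, size=n)
    # empirical-like: deaths cluster in late night / early morning
    mix = rng.random(n) < 0.6
    clustered = np.mod(rng.normal(4.0, 3.0, size=n), 24.0)
    uniform = rng.uniform(0.0, 24.0, size=n)
    return np.where(mix, clustered, uniform)


def _make_subjects(cfg: SimulationConfig, rng: np.random.Generator, preparation: str):
    """Subject-level covariates shared across preparations."""
    n = 2 * cfg.n_per_group
    groups = ["unaffected"] * cfg.n_per_group + ["OUD"] * cfg.n_per_group
    ages = rng.uniform(25.0, 62.0, size=n)
    pmis = rng.uniform(5.0, 30.0, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    tods = _sample_tod(rng, n, cfg.tod_sampling)
    # matched pairs share a TMT plex; 5 pairs per 10-plex block
    pair_index = np.concatenate([np.arange(cfg.n_per_group)] * 2)
    plexes = [f"plex{1 + i // 5}" for i in pair_index]
    subject_ids = [
        f"{'U' if g == 'unaffected' else 'O'}{i % cfg.n_per_group + 1:03d}"
        for i, g in enumerate(groups)
    ]
    return subject_ids, groups, sexes, ages, pmis, plexes, tods


def _plex_offsets(plexes, rng: np.random.Generator, plex_sd: float) -> np.ndarray:
    labels = sorted(set(plexes))
    offs = {lab: rng.normal(0.0, plex_sd) if plex_sd > 0 else 0.0 for lab in labels}
    return np.array([offs[p] for p in plexes])


def _protein_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_proteins
    ids = [f"P{i + 1:05d}" for i in range(n)]
    mesor = rng.normal(cfg.mesor_mean, cfg.mesor_sd, size=n)
    phase = rng.uniform(0.0, 24.0, size=n)

    n_rhythmic = int(round(cfg.frac_rhythmic * n))
    rhythmic_idx = rng.choice(n, size=n_rhythmic, replace=False)
    amp_u = np.zeros(n)
    amp_u[rhythmic_idx] = rng.uniform(*cfg.amplitude_range, size=n_rhythmic)

    amp_o = amp_u.copy()
    n_loss = int(round(cfg.rhythm_loss_frac * n_rhythmic))
    if n_loss:
        loss_idx = rng.choice(rhythmic_idx, size=n_loss, replace=False)
        amp_o[loss_idx] = 0.0
    n_gain = int(round(cfg.rhythm_gain_frac * n))
    if n_gain:
        non_rhythmic = np.setdiff1d(np.arange(n), rhythmic_idx)
        gain_idx = rng.choice(non_rhythmic, size=n_gain, replace=False)
        amp_o[gain_idx] = rng.uniform(*cfg.amplitude_range, size=n_gain)

    n_de = int(round(cfg.frac_de * n))
    logfc = np.zeros(n)
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        logfc[de_idx] = signs * rng.uniform(*cfg.de_logfc_range, size=n_de)

    n_enr = int(round(cfg.frac_enriched * n))
    fold = np.ones(n)
    enriched = np.zeros(n, dtype=bool)
    if n_enr:
        enr_idx = rng.choice(n, size=n_enr, replace=False)
        fold[enr_idx] = rng.uniform(*cfg.enrich_fold_range, size=n_enr)
        enriched[enr_idx] = True

    module = np.array(["grey"] * n, dtype=object)
    if cfg.n_modules:
        mod_idx = rng.choice(n, size=cfg.n_modules * cfg.module_size, replace=False)
        for m in range(cfg.n_modules):
            members = mod_idx[m * cfg.module_size:(m + 1) * cfg.module_size]
            module[members] = f"M{m + 1}"

    return pd.DataFrame(
        dict(
            protein_id=ids,
            mesor=mesor,
            phase=phase,
            amplitude_unaffected=amp_u,
            amplitude_oud=amp_o,
            rhythmic_unaffected=amp_u > 0,
            rhythmic_oud=amp_o > 0,
            true_logfc=logfc,
            enrich_fold=fold,
            enriched=enriched,
            module=module,
        )
    )


def _module_noise(cfg: SimulationConfig, truth: pd.DataFrame, groups: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Residual noise with within-module correlation from shared latent factors.

    For a module member in group g, noise = noise_sd * (sqrt(r_g) * f + sqrt(1-r_g) * e)
    with f a per-(module, sample) factor and e idiosyncratic, so the expected
    pairwise within-module correlation is r_g and the marginal variance stays
    noise_sd**2.
    """
    n, ns = len(truth), len(groups)
    eps = rng.standard_normal((n, ns))
    noise = eps.copy()
    module = truth["module"].to_numpy()
    mod_labels = [m for m in pd.unique(module) if m != "grey"]
    for m in mod_labels:
        f = rng.standard_normal(ns)
        rows = np.flatnonzero(module == m)
        for g, r in cfg.module_cor_by_group.items():
            cols = np.flatnonzero(groups == g)
            if not len(cols):
                continue
            lam = np.sqrt(max(0.0, min(1.0, r)))
            noise[np.ix_(rows, cols)] = (
                lam * f[cols][None, :] + np.sqrt(1.0 - lam ** 2) * eps[np.ix_(rows, cols)]
            )
    return cfg.noise_sd * noise


def _signal_matrix(cfg: SimulationConfig, truth: pd.DataFrame, groups: np.ndarray,
                   zt: np.ndarray, ages: np.ndarray, pmis: np.ndarray,
                   plex_off: np.ndarray) -> np.ndarray:
    amp = np.where(
        groups[None, :] == "OUD",
        truth["amplitude_oud"].to_numpy()[:, None],
        truth["amplitude_unaffected"].to_numpy()[:, None],
    )
    phase = truth["phase"].to_numpy()[:, None]
    mesor = truth["mesor"].to_numpy()[:, None]
    logfc = truth["true_logfc"].to_numpy()[:, None]
    y = mesor + amp * np.cos(2.0 * np.pi * (zt[None, :] - phase) / 24.0)
    y = y + logfc * (groups[None, :] == "OUD")
    cov_values = {"age": ages, "pmi": pmis}
    for name, slope in cfg.covariate_effects.items():
        if name not in cov_values:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        c = cov_values[name]
        y = y + slope * (c - c.mean())[None, :]
    y = y + plex_off[None, :]
    return y


def simulate_cohort(config: SimulationConfig):
    """Simulate one (region, preparation) cohort.

    Returns ``(Dataset, GroundTruth)``.  Generation is a pure function of
    ``config.seed``: the same config yields bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_COHORT,)))
    subject_ids, groups, sexes, ages, pmis, plexes, tods = _make_subjects(cfg, rng, cfg.preparation)
    groups_arr = np.array(groups)
    zt = tod_to_zt(np.array(tods), cfg.sunrise, cfg.sunset)
    plex_off = _plex_offsets(plexes, rng, cfg.plex_sd)
    truth = _protein_truth(cfg, rng)
    y = _signal_matrix(cfg, truth, groups_arr, zt, ages, pmis, plex_off)
    if cfg.noise_sd > 0:
        y = y + _module_noise(cfg, truth, groups_arr, rng)
    prep_tag = cfg.preparation[:3]
    sample_ids = [f"{sid}_{cfg.region}_{prep_tag}" for sid in subject_ids]
    subjects = [
        SubjectRecord(
            sample_id=sample_ids[i], subject_id=subject_ids[i], group=groups[i],
            region=cfg.region, preparation=cfg.preparation, sex=sexes[i],
            age=float(ages[i]), pmi=float(pmis[i]), plex=plexes[i],
            tod_clock=float(tods[i]), sunrise=cfg.sunrise, sunset=cfg.sunset,
        )
        for i in range(len(subject_ids))
    ]
    em = ExpressionMatrix(list(truth["protein_id"]), sample_ids, y, is_log2=True)
    samples_df = pd.DataFrame(
        dict(sample_id=sample_ids, subject_id=subject_ids, group=groups,
             plex=plexes, plex_offset=plex_off, tod=tods, zt=zt)
    )
    return Dataset(em, subjects), GroundTruth(truth, samples_df, cfg)


def simulate_paired_preparations(config: SimulationConfig):
    """Simulate paired homogenate and synaptosome datasets from one cohort.

    The homogenate matrix is generated as in :func:`simulate_cohort`; the
    synaptosome value is the homogenate value plus ``log2(enrichment fold)``
    for planted synapse-enriched proteins plus independent residual noise.
    Subject ids are shared across preparations.

    Returns ``(hom_dataset, syn_dataset, GroundTruth)``.
    """
    cfg = dataclasses.replace(config, preparation="homogenate")
    hom_ds, truth = simulate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(_STREAM_PAIRED,)))
    log2fold = np.log2(truth.proteins["enrich_fold"].to_numpy())[:, None]
    syn_values = hom_ds.expr.values + log2fold
    if cfg.noise_sd > 0:
        syn_values = syn_values + rng.normal(0.0, cfg.noise_sd, size=syn_values.shape)
    syn_sample_ids = [s.subject_id + f"_{cfg.region}_syn" for s in hom_ds.subjects]
    syn_subjects = [
        dataclasses.replace(s, sample_id=sid, preparation="synaptosome")
        for s, sid in zip(hom_ds.subjects, syn_sample_ids)
    ]
    syn_em = ExpressionMatrix(hom_ds.protein_ids, syn_sample_ids, syn_values, is_log2=True)
    return hom_ds, Dataset(syn_em, syn_subjects), truth
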