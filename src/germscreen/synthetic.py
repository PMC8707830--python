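"""Synthetic time-course metabolome generator with planted ground truth.

Emulates a two-variety rice germination study: 2 varieties (``fast``,
``slow``) × 8 time points (0, 3, 6, 9, 12, 24, 36, 48 hours after
imbibition) × 3 replicates, with

* a logistic germination curve whose midpoint is shifted by ``lag_hours``
  for the slow variety,
* a planted subset of germination-associated metabolites whose time-point
  means track (or anti-track) the germination curve linearly,
* background metabolites following trajectory archetypes (monotone
  accumulation, monotone consumption, interior peak, flat),
* multiplicative log-normal replicate noise calibrated so the expected
  replicate coefficient of variation equals ``noise_cv``, and
* optional outlier replicates whose metabolite vector is replaced by an
  unrelated (permuted) profile.

Every stochastic choice flows from one seeded ``numpy`` Generator, so the
same config + seed reproduces the dataset bit for bit.  The generator
returns the planted truth (:class:`SyntheticTruth`) alongside the data so
downstream screening can be scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import InputError, MetabolomeMatrix, validate_phenotype

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "truth_confusion",
    "logistic_germination",
]

DEFAULT_CLASS_PROPORTIONS = {
    "lipids": 0.25,
    "flavonoids": 0.18,
    "amino acids and derivatives": 0.17,
    "polyamines": 0.03,
    "organic acids": 0.05,
    "terpenes": 0.04,
    "nucleotides and derivatives": 0.04,
    "phytohormones": 0.03,
    "sugars": 0.03,
    "vitamins and derivatives": 0.06,
    "others": 0.12,
}

#: archetype mix for NON-associated metabolites; germination-associated
#: metabolites are labelled accumulation/consumption by their planted sign.
DEFAULT_ARCHETYPE_MIX = {
    "flat": 0.55,
    "accumulation": 0.15,
    "consumption": 0.15,
    "accumulation-then-consumption": 0.15,
}


def logistic_germination(t, midpoint: float, steepness: float):
    """Logistic germination fraction g(t) = 1 / (1 + exp(−k·(t − t₀)))."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp(-steepness * (t - midpoint)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated study: 400 metabolites of which 60 are
    germination-associated, eight sampling times over the first 48 h of
    imbibition, three replicates, a slow variety lagging the fast one by
    9 h (within the reported 6–12 h range), and 15% multiplicative
    replicate noise typical of LC–MS intensities.
    """

    n_metabolites: int = 400
    n_associated: int = 60
    positive_fraction: float = 0.6
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX)
    )
    timepoints: Sequence[int] = (0, 3, 6, 9, 12, 24, 36, 48)
    n_replicates: int = 3
    varieties: Sequence[str] = ("fast", "slow")
    lag_hours: float = 9.0
    noise_cv: float = 0.15
    noise_model: str = "lognormal"  # or "additive"
    n_outlier_replicates: int = 0
    effect_size_range: tuple = (3.0, 6.0)
    baseline_floor: float = 0.2
    germination_midpoint: float = 12.0
    germination_steepness: float = 0.3
    seeds_per_dish: int = 50
    plateau_boundaries: Sequence[int] | None = None
    plateau_sigma: float = 0.8
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_associated > self.n_metabolites:
            raise InputError("n_associated must be ≤ n_metabolites")
        if self.lag_hours < 0:
            raise InputError("lag_hours must be ≥ 0")
        if self.noise_cv < 0:
            raise InputError("noise_cv must be ≥ 0")
        if not 0 <= self.positive_fraction <= 1:
            raise InputError("positive_fraction must be in [0, 1]")
        for name, mix in (
            ("class_proportions", self.class_proportions),
            ("archetype_mix", self.archetype_mix),
        ):
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise InputError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in mix.values()):
                raise InputError(f"{name} entries must be ≥ 0")
        if self.noise_model not in ("lognormal", "additive"):
            raise InputError("noise_model must be 'lognormal' or 'additive'")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be ≥ 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_proportions"] = dict(self.class_proportions)
        d["archetype_mix"] = dict(self.archetype_mix)
        d["timepoints"] = list(self.timepoints)
        d["varieties"] = list(self.varieties)
        if self.plateau_boundaries is not None:
            d["plateau_boundaries"] = list(self.plateau_boundaries)
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to the generated data.

    ``metabolites`` has one row per metabolite (associated flag, direction,
    archetype label, effect size); ``samples`` one row per sample (outlier
    flag).  The config and seed are echoed for provenance.
    """

    metabolites: pd.DataFrame
    samples: pd.DataFrame
    config: dict
    seed: int

    @property
    def associated_set(self) -> set:
        return set(self.metabolites.index[self.metabolites["associated"]])

    @property
    def outlier_samples(self) -> set:
        return set(self.samples.index[self.samples["outlier"]])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _counts_from_proportions(n: int, proportions: Mapping[str, float]) -> dict:
    """Largest-remainder allocation of n items to labelled proportions."""
    labels = list(proportions)
    raw = np.array([proportions[k] for k in labels]) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(labels)]] += 1
    return dict(zip(labels, counts.tolist()))


def _mean_trajectories(cfg: SyntheticConfig, truth_rows, params, rng) -> dict:
    """Per-variety (n_metabolites × n_timepoints) mean matrices."""
    tps = np.asarray(cfg.timepoints, dtype=float)
    tmax = float(tps.max())
    out = {}
    for vi, variety in enumerate(cfg.varieties):
        lag = cfg.lag_hours if vi == 1 else 0.0
        eff = np.clip(tps - lag, 0.0, tmax)
        g = logistic_germination(eff, cfg.germination_midpoint, cfg.germination_steepness)
        rows = []
        for row, prm in zip(truth_rows, params):
            base = prm["base"]
            if cfg.plateau_boundaries is not None:
                bounds = list(cfg.plateau_boundaries)
                regime = np.searchsorted(np.asarray(bounds, float), eff, side="left")
                rows.append(base * prm["plateau_levels"][regime])
                continue
            if row["associated"]:
                e = row["effect_size"]
                link = g if row["direction"] > 0 else 1.0 - g
                rows.append(base * (cfg.baseline_floor + e * link))
            else:
                a = prm["amplitude"]
                arch = row["archetype"]
                if arch == "flat":
                    rows.append(np.full_like(eff, base))
                elif arch == "accumulation":
                    rows.append(base * (1.0 + a * eff / tmax))
                elif arch == "consumption":
                    rows.append(base * (1.0 + a * (1.0 - eff / tmax)))
                else:  # interior peak
                    tp, w = prm["peak_time"], prm["peak_width"]
                    rows.append(base * (1.0 + a * np.exp(-((eff - tp) ** 2) / (2 * w**2))))
        out[variety] = np.vstack(rows)
    return out


def generate(config: SyntheticConfig):
    """Generate ``(MetabolomeMatrix, phenotype DataFrame, SyntheticTruth)``.

    Identical config + seed give bit-identical output.  With
    ``noise_cv=0`` and no outliers, the replicates at each variety × time
    point are exactly identical and the phenotype equals the noiseless
    logistic curve.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_metabolites
    tps = list(config.timepoints)

    # -- metabolite-level truth -------------------------------------------
    class_counts = _counts_from_proportions(n, config.class_proportions)
    classes = np.array(
        [c for c, k in class_counts.items() for _ in range(k)], dtype=object
    )
    rng.shuffle(classes)
    met_ids = [f"met{i:04d}" for i in range(n)]

    associated = np.zeros(n, dtype=bool)
    associated[rng.choice(n, size=config.n_associated, replace=False)] = True
    n_pos = int(round(config.positive_fraction * config.n_associated))
    signs = np.zeros(n, dtype=int)
    assoc_idx = np.flatnonzero(associated)
    pos_idx = rng.choice(assoc_idx, size=n_pos, replace=False)
    signs[assoc_idx] = -1
    signs[pos_idx] = 1

    arch_counts = _counts_from_proportions(n - config.n_associated, config.archetype_mix)
    bg_arch = np.array(
        [a for a, k in arch_counts.items() for _ in range(k)], dtype=object
    )
    rng.shuffle(bg_arch)
    archetypes = np.empty(n, dtype=object)
    archetypes[~associated] = bg_arch
    archetypes[associated] = np.where(
        signs[associated] > 0, "accumulation", "consumption"
    )

    effects = np.zeros(n)
    effects[assoc_idx] = rng.uniform(*config.effect_size_range, size=len(assoc_idx))

    truth_rows = [
        {
            "associated": bool(associated[i]),
            "direction": int(signs[i]),
            "archetype": archetypes[i],
            "effect_size": float(effects[i]),
        }
        for i in range(n)
    ]
    n_regimes = (
        len(config.plateau_boundaries) + 1 if config.plateau_boundaries is not None else 0
    )
    params = [
        {
            "base": float(rng.lognormal(np.log(1000.0), 1.0)),
            "amplitude": float(rng.uniform(0.3, 1.0)),
            "peak_time": float(rng.uniform(9.0, 24.0)),
            "peak_width": float(rng.uniform(4.0, 7.0)),
            "plateau_levels": (
                rng.lognormal(0.0, config.plateau_sigma, size=n_regimes)
                if n_regimes
                else None
            ),
        }
        for _ in range(n)
    ]
    means = _mean_trajectories(config, truth_rows, params, rng)

    # -- sample grid and replicate noise ----------------------------------
    sample_rows = []
    blocks = []
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))  # E[CV] = noise_cv
    for vi, variety in enumerate(config.varieties):
        for ti, t in enumerate(tps):
            mu = means[variety][:, ti]
            for rep in range(1, config.n_replicates + 1):
                sid = f"{variety}-{t}h-{rep}"
                sample_rows.append(
                    {"sample_id": sid, "variety": variety, "timepoint_hai": int(t), "replicate": rep}
                )
                if config.noise_cv == 0:
                    vals = mu.copy()
                elif config.noise_model == "lognormal":
                    vals = mu * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
                else:  # additive, truncated at zero
                    vals = np.maximum(mu + rng.normal(0.0, config.noise_cv, size=n) * mu.mean(), 0.0)
                blocks.append(vals)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    values = pd.DataFrame(
        np.vstack(blocks), index=samples.index, columns=pd.Index(met_ids, name="metabolite_id")
    )

    # -- outlier replicates: unrelated profile via within-sample permutation
    outliers = np.zeros(len(samples), dtype=bool)
    if config.n_outlier_replicates:
        pick = rng.choice(len(samples), size=config.n_outlier_replicates, replace=False)
        for i in pick:
            values.iloc[i] = rng.permutation(values.iloc[i].to_numpy())
        outliers[pick] = True

    metabolites = pd.DataFrame(
        {
            "name": met_ids,
            "compound_class": classes,
            "module_tag": "none",
        },
        index=pd.Index(met_ids, name="metabolite_id"),
    )
    matrix = MetabolomeMatrix(samples=samples, metabolites=metabolites, values=values)

    phenotype = _generate_phenotype(config, rng)

    truth = SyntheticTruth(
        metabolites=pd.DataFrame(truth_rows, index=metabolites.index),
        samples=pd.DataFrame({"outlier": outliers}, index=samples.index),
        config=config.to_dict(),
        seed=config.rng_seed,
    )
    return matrix, phenotype, truth


def _water_uptake_percent(t, lag: float):
    """Triphasic water-absorption curve (% of dry weight): fast imbibition
    to ~25% by 12 HAI, a plateau, then renewed uptake after protrusion."""
    eff = np.clip(np.asarray(t, float) - lag, 0.0, None)
    return 25.0 * (1.0 - np.exp(-eff / 5.0)) + 15.0 / (1.0 + np.exp(-0.3 * (eff - 40.0)))


def _generate_phenotype(config: SyntheticConfig, rng) -> pd.DataFrame:
    rows = []
    for vi, variety in enumerate(config.varieties):
        lag = config.lag_hours if vi == 1 else 0.0
        for t in config.timepoints:
            g = float(
                logistic_germination(
                    max(t - lag, 0.0), config.germination_midpoint, config.germination_steepness
                )
            )
            ar = float(_water_uptake_percent(t, lag))
            wb = 0.25
            for rep in range(1, config.n_replicates + 1):
                if config.noise_cv == 0:
                    frac, wa = g, wb * (1 + ar / 100.0)
                else:
                    frac = rng.binomial(config.seeds_per_dish, g) / config.seeds_per_dish
                    # noise on the uptake itself keeps W_a ≥ W_b
                    wa = wb * (1 + ar * float(np.exp(rng.normal(0, 0.05))) / 100.0)
                rows.append(
                    {
                        "variety": variety,
                        "timepoint_hai": int(t),
                        "replicate": rep,
                        "germination_fraction": frac,
                        "fresh_weight": wa,
                        "dry_weight": wb,
                        "treatment": "CK",
                    }
                )
    import warnings

    with warnings.catch_warnings():
        # binomial dish sampling can make sampled means dip; the underlying
        # curve is monotone by construction, so the advisory is noise here
        warnings.simplefilter("ignore", UserWarning)
        return validate_phenotype(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def truth_confusion(recovered, truth: SyntheticTruth) -> dict:
    """Score a recovered candidate set against the planted truth.

    ``recovered`` may be a set of metabolite ids or a
    :class:`~germscreen.screen.ScreeningResult` (its intersection is used).
    Returns the 2×2 counts plus sensitivity (recall of planted positives)
    and precision.  Raises on a metabolite-universe mismatch.
    """
    if hasattr(recovered, "intersection_set"):
        recovered = recovered.intersection_set
    recovered = set(recovered)
    universe = set(truth.metabolites.index)
    stray = recovered - universe
    if stray:
        raise InputError(f"recovered set contains unknown metabolites: {sorted(stray)[:3]}")
    planted = truth.associated_set
    tp = len(recovered & planted)
    fp = len(recovered - planted)
    fn = len(planted - recovered)
    tn = len(universe) - tp - fp - fn
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(recovered) if recovered else float("nan"),
    }
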