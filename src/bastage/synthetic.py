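"""Synthetic biliary-atresia cohorts with known molecular ground truth.

The generator emulates the statistical structure the staging pipeline
assumes: two latent molecular groups (inflammation / fibrosis), a
planted subset of differentially expressed probes with >2-fold log2
effects, ordinal histology scores concordant with the latent group at a
configurable rate (a "seed" subset carries |differential| >= 2, the rest
are mixed with |differential| <= 1), a between-group shift in age at
surgery, and a group-dependent exponential hazard of transplant/death
administratively right-censored at 24 months.  Every draw flows from a
single integer seed, so a configuration reproduces byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .histology import FIBROSIS, INFLAMMATION

AGE_BOUNDS_DAYS = (30.0, 180.0)

# mixed-histology biopsies: fraction with a nonzero (+/-1) differential, and
# the probability that its sign points toward the latent molecular group
MIXED_NONZERO_FRACTION = 17 / 33
MIXED_DIFF_CONCORDANCE = 0.76


class SimConfigError(ValueError):
    """A SimConfig field is out of range or inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator configuration.

    Defaults emulate the study cohort this pipeline targets: 47 infants,
    a 14-sample histology seed subset, 150 signature probes with a mean
    absolute log2 fold change of 1.5, roughly two thirds of planted
    probes up in the inflammation group, group median ages near 55 and
    71 days, and a three-fold fibrosis-vs-inflammation hazard of
    transplant or death censored at 24 months.  ``n_probes`` defaults to
    a desk-scale 2,000-probe array rather than a full genome-wide chip;
    the planted-signature geometry is unchanged by the background size.
    """

    n_samples: int = 47
    n_probes: int = 2000
    n_signature_probes: int = 150
    frac_group_fibrosis: float = 0.6
    log2_effect: float = 1.5
    noise_sd: float = 0.4
    histology_concordance: float = 1.0
    seed_fraction: float = 14 / 47
    seed_group_counts: tuple[int, int] | None = None
    frac_up_inflammation: float = 77 / 115
    age_means_days: tuple[float, float] = (55.0, 71.0)
    age_sd_days: float = 12.0
    hazard_ratio: float = 3.0
    baseline_event_rate: float = 0.02
    censor_months: float = 24.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimConfigError("n_samples must be >= 1")
        if self.n_probes < 1:
            raise SimConfigError("n_probes must be >= 1")
        if not 0 <= self.n_signature_probes <= self.n_probes:
            raise SimConfigError("n_signature_probes must be in 0..n_probes")
        for field in (
            "frac_group_fibrosis",
            "histology_concordance",
            "seed_fraction",
            "frac_up_inflammation",
        ):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{field} must be in [0, 1], got {v}")
        if self.log2_effect < 0:
            raise SimConfigError("log2_effect must be >= 0")
        for field in ("noise_sd", "age_sd_days", "hazard_ratio",
                      "baseline_event_rate", "censor_months"):
            if getattr(self, field) <= 0:
                raise SimConfigError(f"{field} must be > 0")
        if len(self.age_means_days) != 2 or any(a <= 0 for a in self.age_means_days):
            raise SimConfigError("age_means_days must be a pair of positive reals")
        n_seed = round(self.seed_fraction * self.n_samples)
        if self.seed_group_counts is not None:
            si, sf = self.seed_group_counts
            if si < 0 or sf < 0 or si + sf != n_seed:
                raise SimConfigError(
                    "seed_group_counts must be nonnegative and sum to "
                    f"round(seed_fraction * n_samples) = {n_seed}"
                )
            n_fib = round(self.frac_group_fibrosis * self.n_samples)
            if sf > n_fib or si > self.n_samples - n_fib:
                raise SimConfigError(
                    "seed_group_counts exceeds the latent group sizes implied "
                    "by frac_group_fibrosis"
                )


@dataclass(frozen=True)
class CohortTruth:
    """Generator ground truth: latent group per sample, planted probe effects."""

    groups: pd.Series                 # sample_id -> latent label
    planted: pd.DataFrame             # probe_id (index) -> signed log2 effect


@dataclass(frozen=True)
class SyntheticCohort:
    expression: pd.DataFrame          # probes x samples, log2
    samples: pd.DataFrame             # per-sample metadata table
    truth: CohortTruth
    config: SimConfig


def _histology_scores(
    rng: np.random.Generator,
    latent: np.ndarray,
    is_seed: np.ndarray,
    concordance: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (inflammation_grade, fibrosis_stage) pairs, 0..3 each.

    Seed samples get |differential| in {2, 3} whose sign matches the
    latent group with probability ``concordance``; non-seed samples get
    a zero differential or a +/-1 differential whose sign leans toward
    the latent group (weakly informative mixed histology), with both
    scores >= 1 (most biopsies carry some of each lesion).
    Constructive, so the seed fraction holds exactly.
    """
    n = latent.size
    infl = np.zeros(n, dtype=int)
    fib = np.zeros(n, dtype=int)
    for j in range(n):
        if is_seed[j]:
            toward = latent[j]
            if rng.random() >= concordance:
                toward = FIBROSIS if toward == INFLAMMATION else INFLAMMATION
            mag = 2 + int(rng.random() < 0.25)
            low = int(rng.integers(0, 4 - mag))
            if toward == INFLAMMATION:
                infl[j], fib[j] = low + mag, low
            else:
                infl[j], fib[j] = low, low + mag
        else:
            if rng.random() < MIXED_NONZERO_FRACTION:
                toward = latent[j]
                if rng.random() >= MIXED_DIFF_CONCORDANCE:
                    toward = FIBROSIS if toward == INFLAMMATION else INFLAMMATION
                diff = 1 if toward == INFLAMMATION else -1
            else:
                diff = 0
            low = int(rng.integers(1, 4 - abs(diff)))
            if diff >= 0:
                fib[j], infl[j] = low, low + diff
            else:
                infl[j], fib[j] = low, low - diff
    return infl, fib


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a cohort with planted molecular and clinical structure.

    See :class:`SimConfig` for the knobs.  Sample order is randomly
    permuted so position carries no information about the latent group.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_samples

    # latent molecular groups and the histology seed subset
    n_fib = round(cfg.frac_group_fibrosis * n)
    n_seed = round(cfg.seed_fraction * n)
    if cfg.seed_group_counts is not None:
        seed_infl, seed_fib = cfg.seed_group_counts
    else:
        seed_fib = min(round(cfg.frac_group_fibrosis * n_seed), n_fib)
        seed_infl = n_seed - seed_fib
        if seed_infl > n - n_fib:  # tiny cohorts: rebalance
            seed_infl = n - n_fib
            seed_fib = n_seed - seed_infl
    latent = np.array(
        [INFLAMMATION] * seed_infl + [FIBROSIS] * seed_fib
        + [INFLAMMATION] * (n - n_fib - seed_infl)
        + [FIBROSIS] * (n_fib - seed_fib)
    )
    is_seed = np.zeros(n, dtype=bool)
    is_seed[: n_seed] = True
    perm = rng.permutation(n)
    latent, is_seed = latent[perm], is_seed[perm]

    sample_ids = np.array([f"S{j + 1:03d}" for j in range(n)])
    probe_ids = np.array([f"P{i + 1:05d}" for i in range(cfg.n_probes)])

    # expression: background means N(7, 1.5) on the log2 scale, planted
    # probes split +/- log2_effect/2 around their background mean
    base = rng.normal(7.0, 1.5, size=cfg.n_probes)
    planted_idx = rng.choice(cfg.n_probes, size=cfg.n_signature_probes, replace=False)
    n_up = round(cfg.frac_up_inflammation * cfg.n_signature_probes)
    signs = np.concatenate(
        [np.ones(n_up), -np.ones(cfg.n_signature_probes - n_up)]
    )
    signs = signs[rng.permutation(cfg.n_signature_probes)]
    means = np.tile(base[:, None], (1, n))
    infl_mask = latent == INFLAMMATION
    half = cfg.log2_effect / 2.0
    for idx, s in zip(planted_idx, signs):
        means[idx, infl_mask] += s * half
        means[idx, ~infl_mask] -= s * half
    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    expression = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    expression.index.name = "probe_id"

    infl_grade, fib_stage = _histology_scores(
        rng, latent, is_seed, cfg.histology_concordance
    )

    # ages: per-group Gaussian truncated to a plausible surgery window
    lo, hi = AGE_BOUNDS_DAYS
    mu = np.where(infl_mask, cfg.age_means_days[0], cfg.age_means_days[1])
    a = (lo - mu) / cfg.age_sd_days
    b = (hi - mu) / cfg.age_sd_days
    ages = stats.truncnorm.rvs(a, b, loc=mu, scale=cfg.age_sd_days, random_state=rng)

    # outcome: exponential transplant/death times, administrative censoring
    rate = np.where(
        infl_mask, cfg.baseline_event_rate, cfg.baseline_event_rate * cfg.hazard_ratio
    )
    t_event = rng.exponential(1.0 / rate)
    event = (t_event <= cfg.censor_months).astype(int)
    followup = np.minimum(t_event, cfg.censor_months)

    sex = rng.choice(["female", "male"], size=n)
    clinical_type = rng.choice(["perinatal", "BASM"], size=n, p=[0.88, 0.12])
    cholangitis = rng.binomial(1, 0.6, size=n)
    ascites = rng.binomial(1, 0.4, size=n)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "inflammation_grade": infl_grade,
            "fibrosis_stage": fib_stage,
            "age_days": ages,
            "sex": sex,
            "clinical_type": clinical_type,
            "cholangitis": cholangitis,
            "ascites": ascites,
            "followup_months": followup,
            "event": event,
        }
    )

    planted = pd.DataFrame(
        {"log2_effect": signs * cfg.log2_effect},
        index=pd.Index(probe_ids[planted_idx], name="probe_id"),
    ).sort_index()
    truth = CohortTruth(
        groups=pd.Series(latent, index=sample_ids, name="latent_group"),
        planted=planted,
    )
    return SyntheticCohort(
        expression=expression, samples=samples, truth=truth, config=cfg
    )


def write_cohort(cohort: SyntheticCohort, directory: "str | Path") -> dict[str, Path]:
    """Write a cohort to TSV/CSV files that round-trip through the readers.

    Emits ``expression.tsv`` (probes x samples), ``samples.csv``,
    ``truth_samples.csv`` (latent group per sample) and
    ``truth_probes.csv`` (planted probes with signed log2 effects).
    """
    if cohort.samples.shape[0] == 0 or cohort.expression.shape[1] == 0:
        raise ValueError("refusing to write an empty cohort (0 samples)")
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": directory / "expression.tsv",
            "samples": directory / "samples.csv",
            "truth_samples": directory / "truth_samples.csv",
            "truth_probes": directory / "truth_probes.csv",
        }
        cohort.expression.to_csv(paths["expression"], sep="\t")
        cohort.samples.to_csv(paths["samples"], index=False)
        cohort.truth.groups.rename_axis("sample_id").to_csv(paths["truth_samples"])
        cohort.truth.planted.to_csv(paths["truth_probes"])
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return paths


def config_from_mapping(mapping: dict) -> SimConfig:
    """Build a SimConfig from a flat key-value mapping (e.g. parsed YAML)."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise SimConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("age_means_days", "seed_group_counts"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg
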