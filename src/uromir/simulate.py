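"""Synthetic single-channel miRNA microarray cohorts with planted biomarkers.

The generator emulates the signal model the downstream pipeline assumes: each
spot intensity is the sum of a per-array normal background and an
exponentially distributed true signal, truncated at the scanner floor of
zero.  A configurable subset of features is "planted" with monotone cohort
effects (healthy < superficial < advanced, or the reverse), so that every
pipeline stage can be tested against known ground truth without any external
data download.

Cohort labels follow the study design this package targets: HC (healthy
controls), SEC (superficial esophageal cancer) and AEC (advanced esophageal
cancer).  Longitudinal series emit three samples per patient at the
pre-treatment, post-surgery and recurrence timepoints.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

COHORTS = ("HC", "SEC", "AEC")
TIMEPOINTS = ("pre_treatment", "post_surgery", "recurrence")
TREND_SHAPES = ("down_up", "up_down", "flat")

#: Marker ids used for planted features, in the miRBase release-22 vocabulary
#: of cancer-elevated and cancer-reduced urinary miRNAs.
UP_MARKER_NAMES = (
    "hsa-miR-197-3p", "hsa-miR-3085-3p", "hsa-miR-371b-3p", "hsa-miR-3940-3p",
    "hsa-miR-4323", "hsa-miR-4665-3p", "hsa-miR-4763-5p", "hsa-miR-6751-3p",
    "hsa-miR-6775-3p", "hsa-miR-6785-3p", "hsa-miR-6800-3p", "hsa-miR-6824-3p",
    "hsa-miR-6848-3p", "hsa-miR-6872-3p", "hsa-miR-939-3p",
)
DOWN_MARKER_NAMES = ("hsa-miR-10401-5p", "hsa-miR-6831-5p", "hsa-miR-6877-5p")

_SIGNAL_FLOAT_FORMAT = "%.10g"  # serialized decimal precision of fixtures


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Fluorescence is in arbitrary scanner units throughout.  ``effect_sec``
    and ``effect_aec`` multiply the exponential signal mean of planted
    features in the SEC and AEC cohorts; down-planted features use their
    reciprocals, so effects are monotone in disease burden in both
    directions.
    """

    n_hc: int = 20
    n_sec: int = 10
    n_aec: int = 20
    n_features: int = 2632
    n_planted_up: int = 15
    n_planted_down: int = 3
    bg_mean_range: tuple[float, float] = (40.0, 60.0)
    bg_sd_range: tuple[float, float] = (5.0, 10.0)
    signal_mean_baseline: float = 400.0
    effect_sec: float = 8.0
    effect_aec: float = 16.0
    frac_undetectable: float = 0.2
    # baseline-abundance factors for planted features (relative to
    # signal_mean_baseline); down markers start high so a strong decrease
    # still clears the detection filter in the pooled sample set
    planted_factor_up: float = 2.0
    planted_factor_down: float = 8.0
    # log-normal sigma of the per-feature baseline abundance factor
    feature_factor_sigma: float = 0.5
    # exponential mean assigned to "undetectable" features
    undetectable_mean: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hc", "n_sec", "n_aec", "n_features"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_planted_up", "n_planted_down"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_planted_up + self.n_planted_down > self.n_features:
            raise ValueError(
                "n_planted_up + n_planted_down must not exceed n_features "
                f"({self.n_planted_up}+{self.n_planted_down} > {self.n_features})"
            )
        if not (self.effect_aec >= self.effect_sec):
            raise ValueError(
                "effect_aec must be at least effect_sec (monotone disease burden), "
                f"got effect_sec={self.effect_sec}, effect_aec={self.effect_aec}"
            )
        if self.n_planted_up + self.n_planted_down > 0 and not self.effect_sec >= 1.0:
            raise ValueError(
                f"effect_sec must be >= 1 with planted features, got {self.effect_sec}"
            )
        lo, hi = self.bg_sd_range
        if not (0 < lo <= hi):
            raise ValueError(f"bg_sd_range values must be strictly positive, got {self.bg_sd_range}")
        lo, hi = self.bg_mean_range
        if not (lo <= hi):
            raise ValueError(f"bg_mean_range must be ordered, got {self.bg_mean_range}")
        if not self.signal_mean_baseline > 0:
            raise ValueError(
                f"signal_mean_baseline must be strictly positive, got {self.signal_mean_baseline}"
            )
        if not (0.0 <= self.frac_undetectable < 1.0):
            raise ValueError(f"frac_undetectable must be in [0, 1), got {self.frac_undetectable}")
        if self.undetectable_mean <= 0 or self.planted_factor_up <= 0 or self.planted_factor_down <= 0:
            raise ValueError("abundance factors and undetectable_mean must be strictly positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated data set, for recovery tests.

    ``planted`` has one row per planted feature with its direction and the
    multipliers applied to the SEC and AEC exponential means.  ``sample_params``
    records the per-sample background (mu, sigma) actually used, and
    ``feature_baseline`` the per-feature healthy-cohort exponential mean theta.
    """

    planted: pd.DataFrame
    sample_params: pd.DataFrame
    feature_baseline: pd.Series

    @property
    def directions(self) -> dict[str, str]:
        """Mapping feature_id -> 'up' / 'down' for planted features."""
        return dict(zip(self.planted["feature_id"], self.planted["direction"]))


def _feature_layout(config: SimulationConfig, rng: np.random.Generator):
    """Feature ids, baseline exponential means and planted multipliers.

    Deterministic given the generator state; shared by the cohort and the
    longitudinal generators so both see the same feature universe.
    """
    n = config.n_features
    n_up, n_down = config.n_planted_up, config.n_planted_down

    def _names(base: tuple[str, ...], count: int, tag: str) -> list[str]:
        out = list(base[:count])
        out += [f"hsa-miR-sim{tag}-{i:04d}" for i in range(len(out), count)]
        return out

    up_ids = _names(UP_MARKER_NAMES, n_up, "U")
    down_ids = _names(DOWN_MARKER_NAMES, n_down, "D")
    n_bg = n - n_up - n_down
    bg_ids = [f"hsa-miR-sim-{i:04d}" for i in range(n_bg)]
    feature_ids = np.array(up_ids + down_ids + bg_ids, dtype=object)

    factors = rng.lognormal(mean=0.0, sigma=config.feature_factor_sigma, size=n)
    factors[:n_up] = config.planted_factor_up
    factors[n_up:n_up + n_down] = config.planted_factor_down
    baseline = config.signal_mean_baseline * factors

    # undetectable features drawn from the non-planted pool
    n_undet = int(round(config.frac_undetectable * n))
    n_undet = min(n_undet, n_bg)
    undet_idx = rng.choice(np.arange(n_up + n_down, n), size=n_undet, replace=False)
    baseline[undet_idx] = config.undetectable_mean

    # per-cohort multipliers: columns HC, SEC, AEC
    mult = np.ones((n, 3))
    mult[:n_up, 1] = config.effect_sec
    mult[:n_up, 2] = config.effect_aec
    mult[n_up:n_up + n_down, 1] = 1.0 / config.effect_sec
    mult[n_up:n_up + n_down, 2] = 1.0 / config.effect_aec

    direction = np.array(["up"] * n_up + ["down"] * n_down, dtype=object)
    planted = pd.DataFrame(
        {
            "feature_id": feature_ids[: n_up + n_down],
            "direction": direction,
            "effect_sec": mult[: n_up + n_down, 1],
            "effect_aec": mult[: n_up + n_down, 2],
        }
    )

    order = rng.permutation(n)
    return feature_ids[order], baseline[order], mult[order], planted


def _draw_sample(rng, mu, sigma, theta):
    bg = rng.normal(mu, sigma, size=theta.shape)
    sig = rng.exponential(theta)
    return np.maximum(bg + sig, 0.0)  # scanner floor


def generate_cohort_signals(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a raw cohort signal matrix with metadata and ground truth.

    Returns
    -------
    signals : DataFrame, features x samples, nonnegative fluorescence.
    metadata : DataFrame with one row per sample (cohort, patient, covariates).
    truth : SyntheticTruth recording all generation parameters.
    """
    config.validate()
    rng_layout = np.random.default_rng([config.seed, 0])
    rng = np.random.default_rng([config.seed, 1])
    feature_ids, baseline, mult, planted = _feature_layout(config, rng_layout)

    counts = {"HC": config.n_hc, "SEC": config.n_sec, "AEC": config.n_aec}
    sample_ids, cohorts = [], []
    for cohort in COHORTS:
        for i in range(counts[cohort]):
            sample_ids.append(f"{cohort}{i + 1:02d}")
            cohorts.append(cohort)

    n_samples = len(sample_ids)
    mus = rng.uniform(*config.bg_mean_range, size=n_samples)
    sigmas = rng.uniform(*config.bg_sd_range, size=n_samples)

    values = np.empty((config.n_features, n_samples))
    for j, cohort in enumerate(cohorts):
        theta = baseline * mult[:, COHORTS.index(cohort)]
        values[:, j] = _draw_sample(rng, mus[j], sigmas[j], theta)

    signals = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                           columns=sample_ids)
    metadata = _cohort_metadata(sample_ids, cohorts, rng)
    truth = SyntheticTruth(
        planted=planted,
        sample_params=pd.DataFrame(
            {"sample_id": sample_ids, "mu": mus, "sigma": sigmas}
        ),
        feature_baseline=pd.Series(baseline, index=signals.index, name="theta_baseline"),
    )
    return signals, metadata, truth


def _cohort_metadata(sample_ids, cohorts, rng) -> pd.DataFrame:
    """Demographics loosely matching the study population (elderly, mostly
    male, smoking-enriched); purely decorative for the expression analysis."""
    n = len(sample_ids)
    sex = np.where(rng.random(n) < 0.84, "male", "female")
    age = np.clip(rng.normal(68, 8, size=n), 40, 90).round().astype(int)
    smoking = rng.choice(["current", "past", "never"], size=n, p=[0.35, 0.45, 0.2])
    brinkman = np.where(
        smoking == "never", 0, (rng.uniform(200, 1500, size=n)).round().astype(int)
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohorts,
            "patient_id": [f"P_{s}" for s in sample_ids],
            "timepoint": "none",
            "sex": sex,
            "age": age,
            "smoking": smoking,
            "brinkman_index": brinkman,
        }
    )


_SHAPE_SCHEDULE = {
    # multipliers applied to the feature's AEC-scale mean at
    # (pre_treatment, post_surgery, recurrence); the recurrence excursion is
    # slightly larger than pre-treatment ("restored or exceeded")
    "down_up": (1.0, None, 1.25),
    "up_down": (1.0, None, 1.25),
    "flat": (None, None, None),
}


def generate_longitudinal_series(
    config: SimulationConfig,
    n_patients: int,
    patterns: Mapping[str, str],
    exact_signal: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate three-timepoint trajectories for recurrence patients.

    ``patterns`` maps feature ids to a trajectory shape: ``down_up``
    (expression high before treatment, drops after surgery, rises again at
    recurrence — the expected course of a cancer-elevated marker), ``up_down``
    (the mirror image, for cancer-reduced markers) or ``flat``.  Features not
    named keep their healthy-baseline mean at all timepoints.

    With ``exact_signal=True`` the stochastic draws are replaced by their
    means (background at mid-range, signal exactly at theta), producing
    noiseless trajectories for construction-style tests.
    """
    config.validate()
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    for fid, shape in patterns.items():
        if shape not in TREND_SHAPES:
            raise ValueError(
                f"unknown trajectory shape {shape!r} for feature {fid!r}; "
                f"expected one of {TREND_SHAPES}"
            )
    rng_layout = np.random.default_rng([config.seed, 0])
    rng = np.random.default_rng([config.seed, 2])
    feature_ids, baseline, mult, planted = _feature_layout(config, rng_layout)
    index = pd.Index(feature_ids, name="feature_id")
    unknown = set(patterns) - set(feature_ids)
    if unknown:
        raise ValueError(f"pattern features not in the generated matrix: {sorted(unknown)}")

    # per-timepoint multiplier of the baseline mean for each feature
    tp_mult = np.ones((config.n_features, 3))
    pos = {fid: i for i, fid in enumerate(feature_ids)}
    for fid, shape in patterns.items():
        i = pos[fid]
        if shape == "down_up":
            tp_mult[i] = (config.effect_aec, 1.0, config.effect_aec * 1.25)
        elif shape == "up_down":
            tp_mult[i] = (1.0 / config.effect_aec, 1.0, 1.0 / (config.effect_aec * 1.25))

    sample_ids, patient_ids, timepoints = [], [], []
    mus, sigmas = [], []
    cols = []
    for p in range(1, n_patients + 1):
        pid = f"LP{p:02d}"
        if exact_signal:
            mu = float(np.mean(config.bg_mean_range))
            sigma = float(np.mean(config.bg_sd_range))
        else:
            mu = rng.uniform(*config.bg_mean_range)
            sigma = rng.uniform(*config.bg_sd_range)
        for t, tp in enumerate(TIMEPOINTS):
            theta = baseline * tp_mult[:, t]
            if exact_signal:
                col = np.maximum(mu + theta, 0.0)
            else:
                col = _draw_sample(rng, mu, sigma, theta)
            cols.append(col)
            sample_ids.append(f"{pid}_{tp}")
            patient_ids.append(pid)
            timepoints.append(tp)
            mus.append(mu)
            sigmas.append(sigma)

    signals = pd.DataFrame(np.column_stack(cols), index=index, columns=sample_ids)
    n = len(sample_ids)
    rng_meta = np.random.default_rng([config.seed, 3])
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": "AEC",
            "patient_id": patient_ids,
            "timepoint": timepoints,
            "sex": np.repeat(
                np.where(rng_meta.random(n_patients) < 0.84, "male", "female"), 3
            )[:n],
            "age": np.repeat(
                np.clip(rng_meta.normal(66, 6, n_patients), 40, 90).round().astype(int), 3
            )[:n],
            "smoking": np.repeat(
                rng_meta.choice(["current", "past", "never"], n_patients, p=[0.35, 0.45, 0.2]), 3
            )[:n],
            "brinkman_index": 0,
        }
    )
    truth = SyntheticTruth(
        planted=planted,
        sample_params=pd.DataFrame({"sample_id": sample_ids, "mu": mus, "sigma": sigmas}),
        feature_baseline=pd.Series(baseline, index=index, name="theta_baseline"),
    )
    return signals, metadata, truth


# ---------------------------------------------------------------------------
# fixture bundle I/O (TSV dialect shared with the CLI)

def write_signals(signals: pd.DataFrame, path: Path | str) -> None:
    if signals.empty:
        raise ValueError("refusing to write an empty signal matrix")
    signals.to_csv(path, sep="\t", float_format=_SIGNAL_FLOAT_FORMAT,
                   index_label="feature_id")


def read_signals(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    if df.isna().any().any():
        raise ValueError(f"{path}: signal matrix contains missing values")
    return df


def write_metadata(metadata: pd.DataFrame, path: Path | str) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: Path | str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "cohort"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing required columns {sorted(missing)}")
    return meta


def write_truth(truth: SyntheticTruth, path: Path | str) -> None:
    truth.planted.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fixture_bundle(
    signals: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    directory: Path | str,
) -> dict[str, Path]:
    """Write signals.tsv / metadata.tsv / truth.tsv into ``directory``.

    The matrix is serialized with 10 significant digits, which round-trips
    through the readers to that precision.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "signals": directory / "signals.tsv",
            "metadata": directory / "metadata.tsv",
            "truth": directory / "truth.tsv",
        }
        write_signals(signals, paths["signals"])
        write_metadata(metadata, paths["metadata"])
        write_truth(truth, paths["truth"])
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {directory}: {exc}") from exc
    return paths
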