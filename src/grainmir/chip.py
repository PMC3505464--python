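"""miRNA-chip expression analysis across three grain-filling stages.

Background subtraction and per-chip median scaling, detection calls
gated on background-SD multiples, replicate CV, repeat-spot agreement
and an absolute signal floor, stage means and consecutive-stage fold
changes, Student's t-tests on log2 signals, a 2-fold up/down/unchanged
classification, three-stage Venn partitioning of detected probes, a
log2 matrix for clustering, and 2^-ddCt relative quantification for
qRT-PCR follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

STAGES = ("G1", "G2", "G3")

DETECTION_SD_MULTIPLE = 3.0
DETECTION_MAX_CV = 0.5
DETECTION_FLOOR = 32.0
REPEAT_FRACTION_OK = 0.5
MIN_ABUNDANCE = 100.0
FOLD_CUTOFF = 2.0


@dataclass(frozen=True)
class DetectionCall:
    probe_id: str
    stage: str
    detected: bool
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    means: tuple[float, float, float]
    fc_21: float
    fc_32: float
    p_value: float
    regulation: str


def normalize(signals: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    """Background-subtract and median-scale chip signals.

    ``signals`` has columns probe_id, stage, replicate, signal; each
    (stage, replicate) pair is one chip with a row in ``background``
    (stage, replicate, bg_mean, bg_sd).  The chip background mean is
    subtracted (floored at 0), then each chip is scaled so its median
    matches the cross-chip reference median (lower median over chips).
    """
    df = signals.merge(background, on=["stage", "replicate"], how="left")
    if df["bg_mean"].isna().any():
        missing = df[df["bg_mean"].isna()][["stage", "replicate"]]
        raise ValueError(f"missing background for chips:\n{missing}")
    df["signal"] = (df["signal"] - df["bg_mean"]).clip(lower=0.0)
    chip_median = df.groupby(["stage", "replicate"])["signal"].median()
    reference = float(np.percentile(chip_median, 50, method="lower"))
    factors = reference / chip_median
    factors = factors.replace([np.inf, -np.inf], 1.0).fillna(1.0)
    df["signal"] = df["signal"] * df.set_index(["stage", "replicate"]
                                              ).index.map(factors).values
    return df[["probe_id", "stage", "replicate", "signal"]]


def detect(probe_id: str, stage: str, spot_signals: np.ndarray,
           background_sd: float,
           repeat_fraction_ok: float = REPEAT_FRACTION_OK) -> DetectionCall:
    """Detection call for one probe at one stage.

    Detected iff the mean exceeds 3x the background SD, the replicate
    CV is below 0.5, at least half of the individual spots clear the
    3-SD bar, and the mean clears the absolute floor of 32 (signals
    below it are treated as non-expressing).
    """
    x = np.asarray(spot_signals, dtype=float)
    mean = float(x.mean())
    cv = float(x.std(ddof=1) / mean) if mean > 0 else np.inf
    reasons = []
    if mean <= DETECTION_SD_MULTIPLE * background_sd:
        reasons.append("below_3sd")
    if cv >= DETECTION_MAX_CV:
        reasons.append("cv_fail")
    frac_pass = float(np.mean(x > DETECTION_SD_MULTIPLE * background_sd))
    if frac_pass < repeat_fraction_ok:
        reasons.append("repeat_probe_fail")
    if mean < DETECTION_FLOOR:
        reasons.append("below_floor")
    return DetectionCall(probe_id, stage, not reasons, tuple(reasons))


def detection_table(normalized: pd.DataFrame,
                    background: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-stage detection calls on a normalized table."""
    bg_sd = background.groupby("stage")["bg_sd"].mean()
    rows = []
    for (probe, stage), grp in normalized.groupby(["probe_id", "stage"]):
        call = detect(probe, stage, grp["signal"].to_numpy(),
                      float(bg_sd.get(stage, 0.0)))
        rows.append({"probe_id": probe, "stage": stage,
                     "detected": call.detected,
                     "reasons": ",".join(call.reasons)})
    return pd.DataFrame(rows)


def round_half_up(x: float, decimals: int = 2) -> float:
    return float(Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def fold_change(mean_a: float, mean_b: float) -> float:
    """b/a as a 2-decimal half-up-rounded fold."""
    if mean_a <= 0:
        raise ValueError("zero_denominator")
    return round_half_up(mean_b / mean_a, 2)


def differential_test(group_a, group_b, log2: bool = True) -> float:
    """Two-sided Student's t-test between two stages' replicates,
    by default on log2(signal + 1)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("insufficient_replicates")
    if log2:
        a, b = np.log2(a + 1), np.log2(b + 1)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def classify_regulation(means: tuple[float, float, float],
                        min_abundance: float = MIN_ABUNDANCE,
                        fold_cutoff: float = FOLD_CUTOFF) -> str:
    """2-fold rule over consecutive stages.

    Probes never reaching the abundance floor are excluded
    ('low_abundance'); a >=2-fold rise in either consecutive
    comparison is 'up', a <=0.5-fold drop is 'down', both directions at
    once is 'unchanged' (conflicting), otherwise 'unchanged'.
    """
    g1, g2, g3 = means
    if max(means) < min_abundance:
        return "low_abundance"
    fc21 = g2 / g1 if g1 > 0 else np.inf
    fc32 = g3 / g2 if g2 > 0 else np.inf
    up = fc21 >= fold_cutoff or fc32 >= fold_cutoff
    down = fc21 <= 1 / fold_cutoff or fc32 <= 1 / fold_cutoff
    if up and down:
        return "unchanged"
    if up:
        return "up"
    if down:
        return "down"
    return "unchanged"


def de_table(normalized: pd.DataFrame,
             min_abundance: float = MIN_ABUNDANCE,
             fold_cutoff: float = FOLD_CUTOFF) -> pd.DataFrame:
    """Stage means, consecutive fold changes, t-test p-value (G3 vs
    G1 replicates, log2) and regulation class per probe."""
    rows = []
    for probe, grp in normalized.groupby("probe_id"):
        by_stage = {s: g["signal"].to_numpy()
                    for s, g in grp.groupby("stage")}
        if set(STAGES) - set(by_stage):
            continue
        means = tuple(float(by_stage[s].mean()) for s in STAGES)
        try:
            p = differential_test(by_stage["G1"], by_stage["G3"])
        except ValueError:
            p = np.nan
        rows.append({
            "probe_id": probe,
            "mean_G1": means[0], "mean_G2": means[1], "mean_G3": means[2],
            "fc_21": fold_change(means[0], means[1]) if means[0] > 0 else np.nan,
            "fc_32": fold_change(means[1], means[2]) if means[1] > 0 else np.nan,
            "p_value": p,
            "regulation": classify_regulation(means, min_abundance,
                                              fold_cutoff),
        })
    return pd.DataFrame(rows)


def stage_overlap(calls: pd.DataFrame) -> dict[str, int]:
    """Partition probes detected in >=1 stage into the 7 Venn regions
    (keys like 'G1', 'G1&G2', 'G1&G2&G3'); region counts sum to the
    union size."""
    detected = calls[calls["detected"]]
    by_probe = detected.groupby("probe_id")["stage"].apply(frozenset)
    regions = {}
    for r in range(1, 4):
        from itertools import combinations
        for combo in combinations(STAGES, r):
            regions["&".join(combo)] = 0
    for stages in by_probe:
        key = "&".join(s for s in STAGES if s in stages)
        regions[key] += 1
    return regions


def log2_matrix(normalized: pd.DataFrame) -> pd.DataFrame:
    """Probe x stage matrix of log2(mean signal + 1), the input scale
    for clustering/heatmaps."""
    means = normalized.groupby(["probe_id", "stage"])["signal"].mean()
    mat = means.unstack("stage").reindex(columns=list(STAGES))
    return np.log2(mat + 1)


def ddct(ct_target: tuple[float, float],
         ct_reference: tuple[float, float]) -> float:
    """Relative expression by the 2^-ddCt method.

    Each argument is (treated, calibrator) threshold cycles for the
    target and the reference gene; fold = 2 ** -((dCt treated) - (dCt
    calibrator)) with dCt = Ct_target - Ct_reference.
    """
    d_treated = ct_target[0] - ct_reference[0]
    d_calib = ct_target[1] - ct_reference[1]
    return float(2.0 ** -(d_treated - d_calib))
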