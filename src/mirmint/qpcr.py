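"""qPCR quantification: amplification efficiency, reference-gene stability,
efficiency-corrected relative expression, and randomization testing.

The quantification chain mirrors standard real-time PCR practice:

1. Per-well amplification efficiency ``E`` (1 < E <= 2, E = 2 is perfect
   doubling) is estimated by a window-of-linearity regression of
   log10(fluorescence) on cycle within the exponential phase.
2. Candidate reference genes are ranked by the geNorm stability measure
   ``M`` — the mean standard deviation of pairwise log2 expression ratios —
   with iterative exclusion of the least stable candidate and the pairwise
   variation ``V(n/n+1)`` between successive normalization factors.
3. Relative expression between two groups is the efficiency-corrected
   delta-delta-Ct ratio: ``E_target**dCt_target`` divided by the geometric
   mean of ``E_ref**dCt_ref`` over the reference set, where
   ``dCt = mean(Ct_control) - mean(Ct_treated)``.
4. Significance is assessed with a pair-wise fixed-reallocation
   randomization test: group labels are repeatedly reshuffled (group sizes
   fixed) and the ratio recomputed; the two-sided p-value uses the
   (count + 1)/(N + 1) convention so it is never exactly zero.

The module also houses the exact Mann-Whitney U test used for
anatomical-trait group comparisons (exact enumeration for small groups,
normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, NoExponentialPhaseError

__all__ = [
    "AmplificationCurve",
    "EfficiencyEstimate",
    "estimate_efficiency",
    "StabilityResult",
    "genorm_stability",
    "relative_expression",
    "rest_randomization_test",
    "RelativeExpression",
    "RelativeExpressionResults",
    "mann_whitney_exact",
]


# ----------------------------------------------------------------- curves

@dataclass(frozen=True)
class AmplificationCurve:
    """One well's raw amplification trace.

    Cycles must be strictly increasing and fluorescence strictly positive.
    """

    well: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        cycles = np.asarray(self.cycles, dtype=int)
        fluo = np.asarray(self.fluorescence, dtype=float)
        if cycles.shape != fluo.shape or cycles.ndim != 1:
            raise InputError("cycles and fluorescence must be 1-D and equal length")
        if len(cycles) == 0:
            raise InputError("empty amplification curve")
        if np.any(np.diff(cycles) <= 0):
            raise InputError("cycles must be strictly increasing")
        if np.any(fluo <= 0) or not np.all(np.isfinite(fluo)):
            raise InputError("fluorescence must be finite and > 0")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluo)

    def __len__(self):
        return len(self.cycles)


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Window-of-linearity fit for one amplification curve.

    ``ok`` is False when no window reached ``min_r2``; the best fit found is
    still reported for diagnostics.  ``exceeds_doubling`` flags estimates
    above the physical maximum E = 2 (the raw estimate is reported, never
    silently clamped).
    """

    well: str
    efficiency: float
    slope: float
    r_squared: float
    window_start: int
    window_width: int
    ok: bool
    exceeds_doubling: bool


def _baseline_threshold(fluo: np.ndarray, n_baseline: int, factor: float) -> float:
    return factor * float(np.median(fluo[: min(n_baseline, len(fluo))]))


def estimate_efficiency(
    curve: AmplificationCurve,
    window_width: int = 5,
    min_r2: float = 0.99,
    baseline_cycles: int = 5,
    baseline_factor: float = 3.0,
) -> EfficiencyEstimate:
    """Estimate amplification efficiency from the exponential phase.

    Among all windows of ``window_width`` consecutive above-baseline cycles,
    the regression of log10(fluorescence) on cycle with positive slope and
    maximal R-squared is selected; E = 10**slope.  "Above baseline" means
    fluorescence exceeding ``baseline_factor`` times the median of the first
    ``baseline_cycles`` cycles.

    Raises
    ------
    NoExponentialPhaseError
        If no window of above-baseline cycles exists, or every candidate
        window has non-positive slope (e.g. a curve entirely at plateau).
    """
    if window_width < 3:
        raise ConfigurationError("window_width must be >= 3")
    fluo = curve.fluorescence
    cycles = curve.cycles.astype(float)
    above = fluo > _baseline_threshold(fluo, baseline_cycles, baseline_factor)

    # candidate windows: runs of consecutive above-baseline cycles
    candidates = []
    for start in range(0, len(fluo) - window_width + 1):
        stop = start + window_width
        if above[start:stop].all():
            candidates.append((start, stop))
    if not candidates:
        raise NoExponentialPhaseError(
            f"well {curve.well!r}: no window of {window_width} consecutive above-baseline cycles"
        )

    best = None  # (r2, slope, start)
    for start, stop in candidates:
        x = cycles[start:stop]
        y = np.log10(fluo[start:stop])
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        if best is None or r2 > best[0]:
            best = (r2, float(slope), start)
    if best is None:
        raise NoExponentialPhaseError(f"well {curve.well!r}: no exponential phase (no positive-slope window)")

    r2, slope, start = best
    eff = 10.0**slope
    return EfficiencyEstimate(
        well=curve.well,
        efficiency=eff,
        slope=slope,
        r_squared=r2,
        window_start=int(curve.cycles[start]),
        window_width=window_width,
        ok=r2 >= min_r2,
        exceeds_doubling=eff > 2.0 + 1e-9,
    )


def curves_from_frame(df: pd.DataFrame) -> list[AmplificationCurve]:
    """Split a tidy curves table (well, cycle, fluorescence) into curves."""
    out = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("cycle")
        out.append(AmplificationCurve(str(well), sub["cycle"].to_numpy(), sub["fluorescence"].to_numpy()))
    return out


# ----------------------------------------------------------------- geNorm

@dataclass(frozen=True)
class StabilityResult:
    """geNorm stability analysis of candidate reference genes.

    ``m_values`` are the full-panel M values; ``ranking`` lists candidates
    from most to least stable (the final surviving pair first, ordered by
    their last-round M then id); ``exclusion_order`` records the iterative
    removals (least stable first); ``pairwise_variation`` maps n ->
    V(n/n+1) for the n most stable candidates.
    """

    m_values: pd.Series
    ranking: list[str]
    exclusion_order: list[str]
    pairwise_variation: dict[int, float] = field(default_factory=dict)


def _ct_to_quantity(ct_wide: pd.DataFrame, efficiencies: dict[str, float] | None) -> pd.DataFrame:
    """Relative quantities q = E**(Ct_min - Ct), per target (row)."""
    eff = pd.Series({t: (efficiencies or {}).get(t, 2.0) for t in ct_wide.index}, dtype=float)
    if ((eff <= 1) | (eff > 2)).any():
        bad = eff[(eff <= 1) | (eff > 2)].index[0]
        raise InputError(f"efficiency for target {bad!r} outside (1, 2]")
    delta = ct_wide.min(axis=1).to_numpy()[:, None] - ct_wide.to_numpy()
    q = eff.to_numpy()[:, None] ** delta
    return pd.DataFrame(q, index=ct_wide.index, columns=ct_wide.columns)


def _ct_wide(ct: pd.DataFrame, targets=None) -> pd.DataFrame:
    """Pivot a tidy Ct table to targets x samples, validating completeness."""
    wide = ct.pivot_table(index="target", columns="sample", values="ct", aggfunc="mean")
    if targets is not None:
        missing_targets = [t for t in targets if t not in wide.index]
        if missing_targets:
            raise InputError(f"missing Ct rows for target(s) {missing_targets}")
        wide = wide.loc[list(targets)]
    if wide.isna().any().any():
        t = wide.index[wide.isna().any(axis=1)][0]
        s = wide.columns[wide.loc[t].isna()][0]
        raise InputError(f"missing Ct value for target {t!r} in sample {s!r}")
    return wide


def _mean_pairwise_sd(logq: pd.DataFrame) -> pd.Series:
    """geNorm M: for each target j, mean over k != j of sd(log2 q_j - log2 q_k)."""
    targets = list(logq.index)
    m = {}
    for j in targets:
        sds = [float(np.std(logq.loc[j] - logq.loc[k], ddof=1)) for k in targets if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m).sort_index()


def genorm_stability(ct: pd.DataFrame, efficiencies: dict[str, float] | None = None) -> StabilityResult:
    """Rank candidate reference targets by geNorm expression stability.

    Parameters
    ----------
    ct : tidy DataFrame with columns (sample, target, ct); every candidate
        target must have a Ct in every sample.
    efficiencies : optional per-target amplification efficiencies (default 2).

    The M value of a candidate is the arithmetic mean of the standard
    deviations of its pairwise log2 expression ratios against every other
    candidate; low M = stable.  Candidates are excluded iteratively (highest
    M first, ties broken by lexicographic id) until two remain.  V(n/n+1) is
    the standard deviation across samples of the log2 ratio of normalization
    factors (geometric means) built from the n versus n+1 most stable
    candidates.
    """
    wide = _ct_wide(ct)
    if wide.shape[0] < 3:
        raise InputError(f"geNorm needs >= 3 candidate targets, got {wide.shape[0]}")
    if wide.shape[1] < 2:
        raise InputError("geNorm needs >= 2 samples")

    logq = np.log2(_ct_to_quantity(wide, efficiencies))
    m_full = _mean_pairwise_sd(logq)

    remaining = list(logq.index)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m_now = _mean_pairwise_sd(logq.loc[remaining])
        # highest M excluded first; lexicographic id breaks exact ties
        worst = sorted(m_now.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        exclusion.append(worst)
        remaining.remove(worst)
    final_m = _mean_pairwise_sd(logq.loc[sorted(remaining)]) if len(remaining) == 2 else None
    last_two = sorted(remaining, key=lambda t: (final_m[t], t)) if final_m is not None else remaining
    ranking = last_two + list(reversed(exclusion))

    # V(n/n+1) over the stability ranking
    pairwise_variation: dict[int, float] = {}
    for n in range(2, len(ranking)):
        nf_n = logq.loc[ranking[:n]].mean(axis=0)
        nf_n1 = logq.loc[ranking[: n + 1]].mean(axis=0)
        pairwise_variation[n] = float(np.std(nf_n - nf_n1, ddof=1))

    return StabilityResult(
        m_values=m_full,
        ranking=ranking,
        exclusion_order=exclusion,
        pairwise_variation=pairwise_variation,
    )


# -------------------------------------------------- relative expression / REST

def _group_masks(samples: list[str], groups: pd.Series, control: str, treated: str):
    lab = groups.reindex(samples)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])
        raise InputError(f"sample(s) {missing} missing from the sample map")
    ctrl = (lab == control).to_numpy()
    trt = (lab == treated).to_numpy()
    if ctrl.sum() < 2 or trt.sum() < 2:
        raise InputError(f"need >= 2 samples per group; got {int(ctrl.sum())} {control!r} / {int(trt.sum())} {treated!r}")
    return ctrl, trt


def _log2_efficiencies(targets, efficiencies) -> np.ndarray:
    eff = np.array([(efficiencies or {}).get(t, 2.0) for t in targets], dtype=float)
    if np.any((eff <= 1) | (eff > 2)):
        bad = np.asarray(targets)[(eff <= 1) | (eff > 2)][0]
        raise InputError(f"efficiency for target {bad!r} outside (1, 2]")
    return np.log2(eff)


def _combined_signal(ct_wide: pd.DataFrame, target: str, references: list[str], efficiencies) -> np.ndarray:
    """Per-sample signal v such that log2 ratio = w @ v for group weights w.

    v = log2(E_t) * Ct_t - mean_r(log2(E_r) * Ct_r); with dCt weights w
    (+1/n_ctrl on control, -1/n_trt on treated), w @ v equals
    log2(E_t**dCt_t / geometric-mean_r E_r**dCt_r).
    """
    log2e_t = _log2_efficiencies([target], efficiencies)[0]
    log2e_r = _log2_efficiencies(references, efficiencies)
    vt = log2e_t * ct_wide.loc[target].to_numpy()
    vr = (log2e_r[:, None] * ct_wide.loc[references].to_numpy()).mean(axis=0)
    return vt - vr


def relative_expression(
    ct: pd.DataFrame,
    target: str,
    references: list[str],
    groups: pd.Series,
    efficiencies: dict[str, float] | None = None,
    control: str = "control",
    treated: str = "case",
) -> float:
    """Efficiency-corrected relative expression ratio (treated vs control).

    ratio = E_target**dCt_target / NF with dCt = mean(Ct_control) -
    mean(Ct_treated) and NF the geometric mean of E_ref**dCt_ref over the
    reference set.  Efficiencies default to 2 (classic 2**-ddCt).
    """
    if not references:
        raise InputError("empty reference set: normalization requires >= 1 reference target")
    wide = _ct_wide(ct, targets=[target, *references])
    samples = list(wide.columns)
    ctrl, trt = _group_masks(samples, groups, control, treated)
    w = ctrl / ctrl.sum() - trt / trt.sum()
    v = _combined_signal(wide, target, list(references), efficiencies)
    return float(2.0 ** (w @ v))


@dataclass(frozen=True)
class RelativeExpressionResults:
    """Per-target relative expression with randomization p-values."""

    table: pd.DataFrame  # columns: target, ratio, log2_ratio, p_value, n_permutations
    control: str
    treated: str
    references: tuple[str, ...]

    def summary(self) -> str:
        lines = [
            "Relative expression (efficiency-corrected ddCt, randomization test)",
            f"  contrast: {self.treated} vs {self.control}",
            f"  references: {', '.join(self.references)}",
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


class RelativeExpression:
    """Relative-expression model for one or more targets against a reference set.

    Parameters
    ----------
    ct : tidy Ct table with columns (sample, target, ct).
    groups : Series mapping sample id -> group label (two groups).
    targets : targets to quantify; defaults to every non-reference target.
    references : reference targets used for normalization (required).
    efficiencies : optional per-target amplification efficiencies in (1, 2];
        targets without an entry use E = 2.

    ``fit`` runs the pair-wise fixed-reallocation randomization test for each
    target and returns :class:`RelativeExpressionResults`.
    """

    def __init__(
        self,
        ct: pd.DataFrame,
        groups: pd.Series,
        references: list[str],
        targets: list[str] | None = None,
        efficiencies: dict[str, float] | None = None,
        control: str = "control",
        treated: str = "case",
    ):
        if not references:
            raise InputError("empty reference set: normalization requires >= 1 reference target")
        self.ct = ct
        self.groups = groups
        self.references = list(references)
        all_targets = sorted(set(ct["target"]) - set(references))
        self.targets = list(targets) if targets is not None else all_targets
        self.efficiencies = efficiencies
        self.control = control
        self.treated = treated

    def fit(self, n_permutations: int = 10_000, seed: int | None = None) -> RelativeExpressionResults:
        rows = []
        rng = np.random.default_rng(seed)
        for target in self.targets:
            ratio, p = rest_randomization_test(
                self.ct,
                target,
                self.references,
                self.groups,
                efficiencies=self.efficiencies,
                n_permutations=n_permutations,
                seed=rng.integers(2**31),
                control=self.control,
                treated=self.treated,
            )
            rows.append((target, ratio, math.log2(ratio), p, n_permutations))
        table = pd.DataFrame(rows, columns=["target", "ratio", "log2_ratio", "p_value", "n_permutations"])
        return RelativeExpressionResults(
            table=table, control=self.control, treated=self.treated, references=tuple(self.references)
        )


def rest_randomization_test(
    ct: pd.DataFrame,
    target: str,
    references: list[str],
    groups: pd.Series,
    efficiencies: dict[str, float] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    control: str = "control",
    treated: str = "case",
) -> tuple[float, float]:
    """Pair-wise fixed-reallocation randomization test for one target.

    The observed statistic is the efficiency-corrected expression ratio; the
    null distribution reallocates samples between the two groups (sizes
    fixed) and recomputes the ratio.  Returns ``(ratio, p)`` with the
    two-sided p-value (count of |log2 ratio_perm| >= |log2 ratio_obs|, plus
    one, over n_permutations + 1) — never exactly zero by construction.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    if not references:
        raise InputError("empty reference set: normalization requires >= 1 reference target")
    wide = _ct_wide(ct, targets=[target, *references])
    samples = list(wide.columns)
    ctrl, trt = _group_masks(samples, groups, control, treated)
    keep = ctrl | trt
    v = _combined_signal(wide, target, list(references), efficiencies)[keep]
    n_ctrl, n_trt = int(ctrl.sum()), int(trt.sum())
    n = n_ctrl + n_trt

    w_obs = np.where(ctrl[keep], 1.0 / n_ctrl, -1.0 / n_trt)
    obs = float(w_obs @ v)

    rng = np.random.default_rng(seed)
    # each row: a random reallocation keeping group sizes fixed
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    base = np.concatenate([np.full(n_ctrl, 1.0 / n_ctrl), np.full(n_trt, -1.0 / n_trt)])
    weights = np.empty((n_permutations, n))
    np.put_along_axis(weights, order, np.broadcast_to(base, (n_permutations, n)), axis=1)
    perm = weights @ v

    count = int(np.sum(np.abs(perm) >= abs(obs) - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return float(2.0**obs), float(p)


# ----------------------------------------------------------- Mann-Whitney

def _u_statistic(ranks: np.ndarray, idx_a, n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2)


def mann_whitney_exact(group_a, group_b, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney U test, exact for small groups.

    For ``min(n_a, n_b) <= exact_max_n`` the p-value is computed from the
    full permutation distribution of U over all C(n_a + n_b, n_a) label
    assignments of the observed pooled values (mid-ranks for ties; the
    two-sided p is the probability of |U - n_a*n_b/2| at least as large as
    observed).  Larger samples fall back to the normal approximation with
    tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    n_a, n_b, n = a.size, b.size, a.size + b.size

    if min(n_a, n_b) > exact_max_n:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False).pvalue)

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    center = n_a * n_b / 2.0
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    dev_obs = abs(u_obs - center)

    total = math.comb(n, n_a)
    extreme = 0
    for combo in itertools.combinations(range(n), n_a):
        u = _u_statistic(ranks, combo, n_a)
        if abs(u - center) >= dev_obs - 1e-9:
            extreme += 1
    return extreme / total
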