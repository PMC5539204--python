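"""Array-style differential expression: quantile normalization and the
empirical-Bayes moderated t-test.

The moderated t shrinks per-feature sample variances toward a common prior.
With per-feature pooled variance ``s2_g`` on ``d = n1 + n2 - 2`` degrees of
freedom, the prior ``(d0, s0^2)`` is fitted by matching the first two
moments of ``log s2_g`` to a scaled-F distribution (digamma/trigamma moment
equations, solved with a Newton inverse of the trigamma function).  The
posterior variance is

    s2_tilde_g = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated t ``log2FC / (s_tilde_g * sqrt(1/n1 + 1/n2))`` is referred
to a t distribution on ``d0 + d`` degrees of freedom.  ``d0 = 0`` recovers
the ordinary two-sample t-test; ``d0 = inf`` pools all features to ``s0^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

__all__ = [
    "quantile_normalize",
    "DifferentialExpression",
    "DEResults",
    "filter_de",
    "fit_f_dist_moments",
    "trigamma_inverse",
]


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a features x samples matrix.

    Every column is mapped onto the across-column mean of sorted values, so
    all normalized columns share an identical sorted vector while each
    column's rank order is preserved.  Ties receive the average of the
    reference values at the tied rank positions.  Idempotent.
    """
    if m.shape[1] < 2:
        raise InputError("quantile normalization needs >= 2 samples")
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise InputError("expression matrix contains missing values")
    reference = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    positions = np.arange(n, dtype=float)
    for j in range(values.shape[1]):
        # average ranks map ties onto the mean of adjacent reference values
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-10:
            break
    return x


def fit_f_dist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit the scaled-F prior (d0, s0^2) to observed variances by moments.

    Matches mean and variance of ``log s2`` against the theoretical moments
    of ``s0^2 * F(df, d0)``; returns ``(d0, s0sq)`` with ``d0 = inf`` when
    the observed spread of log-variances is no larger than expected from
    sampling alone (no feature-to-feature variance heterogeneity).
    Zero variances are excluded from moment estimation.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        # degenerate panel: no information about spread; pool everything
        s0sq = float(positive.mean()) if positive.size else 0.0
        return math.inf, s0sq
    z = np.log(positive)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid_var = e_var - float(special.polygamma(1, df / 2.0))
    if resid_var <= 0:
        # no excess spread beyond sampling noise: infinite prior df, and the
        # scale reduces to the arithmetic mean of the observed variances
        return math.inf, float(np.mean(s2))
    d0 = 2.0 * trigamma_inverse(resid_var)
    s0sq = float(math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0sq


@dataclass(frozen=True)
class DEResults:
    """Differential-expression fit results.

    ``table`` holds one row per feature: log2fc, t (ordinary), t_moderated,
    p, p_adj (Benjamini-Hochberg), direction (for the default fold/p filter).
    ``d0`` and ``s0sq`` are the fitted prior degrees of freedom and prior
    variance of the empirical-Bayes shrinkage.
    """

    table: pd.DataFrame
    d0: float
    s0sq: float
    n_per_group: tuple[int, int]
    groups: tuple[str, str]

    def summary(self, fc_cut: float = 1.5, p_cut: float = 0.05, use_adjusted: bool = False) -> str:
        up, down = self.filter(fc_cut=fc_cut, p_cut=p_cut, use_adjusted=use_adjusted)
        head = self.table.sort_values("p").head(10)
        lines = [
            "Moderated t-test (empirical-Bayes shrunken variances)",
            f"  contrast: {self.groups[1]} vs {self.groups[0]}  (n = {self.n_per_group[1]} vs {self.n_per_group[0]})",
            f"  prior df d0 = {self.d0:.4g}, prior variance s0^2 = {self.s0sq:.4g}",
            f"  features: {len(self.table)}; at fold >= {fc_cut}, p <= {p_cut}"
            f"{' (adjusted)' if use_adjusted else ''}: {len(up)} up, {len(down)} down",
            "",
            "Top features by p-value:",
            head.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def filter(self, fc_cut: float = 1.5, p_cut: float = 0.05, use_adjusted: bool = False):
        return filter_de(self.table, fc_cut=fc_cut, p_cut=p_cut, use_adjusted=use_adjusted)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t", float_format="%.6g")

    def plot_volcano(self, ax=None, p_cut: float = 0.05, fc_cut: float = 1.5):
        """Volcano plot (log2 fold change vs -log10 p); requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        sig = (t["p"] <= p_cut) & (2.0 ** t["log2fc"].abs() >= fc_cut)
        ax.scatter(t["log2fc"][~sig], -np.log10(t["p"][~sig]), s=6, c="grey", alpha=0.5)
        ax.scatter(t["log2fc"][sig], -np.log10(t["p"][sig]), s=8, c="crimson")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        return ax


class DifferentialExpression:
    """Two-group moderated t-test model for a log2 expression matrix.

    Parameters
    ----------
    data : features x samples DataFrame of log2-scale values (no missing
        entries).
    groups : Series mapping sample id -> group label; exactly two groups,
        each with >= 2 samples.
    reference : label of the reference (control) group; fold changes are
        ``other - reference`` means.  Defaults to the lexicographically
        smaller label.
    """

    def __init__(self, data: pd.DataFrame, groups: pd.Series, reference: str | None = None):
        lab = groups.reindex(data.columns)
        if lab.isna().any():
            missing = list(lab.index[lab.isna()])
            raise InputError(f"sample(s) {missing} missing from the sample map")
        if data.isna().any().any():
            raise InputError("expression matrix contains missing values")
        levels = sorted(lab.unique())
        if len(levels) != 2:
            raise InputError(f"exactly two groups required, got {levels}")
        if reference is None:
            reference = levels[0]
        if reference not in levels:
            raise InputError(f"reference group {reference!r} not among {levels}")
        other = levels[0] if reference == levels[1] else levels[1]
        self.data = data
        self.groups = (reference, other)
        self._mask1 = (lab == reference).to_numpy()
        self._mask2 = (lab == other).to_numpy()
        if self._mask1.sum() < 2 or self._mask2.sum() < 2:
            raise InputError("each group needs >= 2 samples")

    @classmethod
    def from_files(cls, expression_path, sample_map_path, reference: str | None = None):
        from . import io

        return cls(io.read_expression(expression_path), io.read_sample_map(sample_map_path), reference=reference)

    def fit(self, d0: float | None = None, s0sq: float | None = None) -> DEResults:
        """Fit the moderated t-test.

        ``d0``/``s0sq`` override the empirical-Bayes prior (``d0 = 0`` gives
        the ordinary t-test; ``d0 = inf`` uses the prior variance alone).
        """
        x = self.data.to_numpy(dtype=float)
        n1, n2 = int(self._mask1.sum()), int(self._mask2.sum())
        m1 = x[:, self._mask1].mean(axis=1)
        m2 = x[:, self._mask2].mean(axis=1)
        log2fc = m2 - m1
        ss1 = ((x[:, self._mask1] - m1[:, None]) ** 2).sum(axis=1)
        ss2 = ((x[:, self._mask2] - m2[:, None]) ** 2).sum(axis=1)
        df = n1 + n2 - 2
        s2 = (ss1 + ss2) / df
        se_factor = math.sqrt(1.0 / n1 + 1.0 / n2)

        if d0 is None:
            d0_fit, s0sq_fit = fit_f_dist_moments(s2, df)
        else:
            d0_fit = float(d0)
            s0sq_fit = float(s0sq) if s0sq is not None else fit_f_dist_moments(s2, df)[1]

        if math.isinf(d0_fit):
            s2_post = np.full_like(s2, s0sq_fit)
            df_total = np.inf
        else:
            s2_post = (d0_fit * s0sq_fit + df * s2) / (d0_fit + df)
            df_total = d0_fit + df

        with np.errstate(divide="ignore", invalid="ignore"):
            t_ord = log2fc / np.sqrt(s2 * se_factor**2)
            t_mod = log2fc / np.sqrt(s2_post * se_factor**2)
        # zero posterior variance: infinite evidence unless the effect is zero too
        t_mod = np.where(np.isnan(t_mod) & (log2fc == 0), 0.0, t_mod)
        t_ord = np.where(np.isnan(t_ord) & (log2fc == 0), 0.0, t_ord)

        if math.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p = np.where(np.isinf(t_mod), 0.0, p)
        p = np.clip(p, 0.0, 1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]

        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "t": t_ord,
                "t_moderated": t_mod,
                "p": p,
                "p_adj": p_adj,
            },
            index=self.data.index,
        )
        up, down = filter_de(table)
        direction = pd.Series("ns", index=table.index)
        direction.loc[up] = "up"
        direction.loc[down] = "down"
        table["direction"] = direction
        return DEResults(table=table, d0=d0_fit, s0sq=s0sq_fit, n_per_group=(n1, n2), groups=self.groups)


def filter_de(
    table: pd.DataFrame, fc_cut: float = 1.5, p_cut: float = 0.05, use_adjusted: bool = False
) -> tuple[list[str], list[str]]:
    """Split features into up/down lists by linear fold-change and p cutoffs.

    ``fc_cut`` is a linear-scale fold change (>= 1); a feature is "up" when
    ``2**log2fc >= fc_cut`` and its (raw or adjusted) p-value is <= ``p_cut``,
    "down" when ``2**(-log2fc) >= fc_cut`` under the same p rule.
    """
    if fc_cut < 1:
        raise ConfigurationError(f"fc_cut must be >= 1 (linear fold change), got {fc_cut}")
    pcol = "p_adj" if use_adjusted else "p"
    fold = 2.0 ** table["log2fc"]
    sig = table[pcol] <= p_cut
    up = list(table.index[(fold >= fc_cut) & sig])
    down = list(table.index[(1.0 / fold >= fc_cut) & sig])
    return up, down
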