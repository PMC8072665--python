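"""Two-group differential expression with an empirical-Bayes moderated t.

Microarray-style log2 expression matrices are screened gene-by-gene for
case/control differences.  The per-gene pooled variance s_g^2 (d residual
degrees of freedom) is shrunk towards a prior variance s0^2 with d0 prior
degrees of freedom fitted by moment matching on log s_g^2:

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_g    = log2FC_g / sqrt(s~_g^2 * (1/n1 + 1/n2)),   df = d0 + d

The hyperparameters come from matching the mean and variance of
e_g = log s_g^2 - digamma(d/2) + log(d/2) against the theoretical scaled-F
moments: Var[e] ~ trigamma(d/2) + trigamma(d0/2), solved for d0 by Newton
inversion of the trigamma function.  When the observed dispersion of log s^2
does not exceed the chi-square sampling noise, d0 = +inf and every gene
variance shrinks fully to s0^2 (the t reduces to a z statistic).

Significance calls follow the permissive screening rule p < p_max (strict)
and |log2FC| > lfc_min (strict), with an optional BH-FDR criterion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"

P_MAX_DEFAULT = 0.05
LFC_MIN_DEFAULT = 0.05


class ExpressionError(ValueError):
    """Invalid expression profile or group labelling."""


@dataclass
class ExpressionProfile:
    """Gene x sample log2 expression matrix with a two-group design.

    ``values`` is a DataFrame indexed by gene symbol with sample columns;
    ``groups`` maps every sample to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ExpressionError(f"samples without a group label: {missing}")
        bad = {g for g in self.groups.values()} - {CASE, CONTROL}
        if bad:
            raise ExpressionError(f"unknown group labels: {sorted(bad)}")
        for grp in (CASE, CONTROL):
            if len(self.samples(grp)) < 2:
                raise ExpressionError(f"group {grp!r} needs >= 2 samples")
        if self.values.index.hasnans or (self.values.index == "").any():
            raise ExpressionError("missing gene symbols in matrix index")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            log.warning(
                "duplicate gene symbols (%d); keeping first occurrence", len(dup)
            )
            self.values = self.values[~self.values.index.duplicated(keep="first")]

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, groups_path: str | Path) -> "ExpressionProfile":
        """Read a TSV matrix (first column = gene symbol) and a two-column
        sample/group TSV."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        gr = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
        return cls(values=values, groups=dict(zip(gr["sample"].astype(str), gr["group"])))

    def to_tsv(self, matrix_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.6f")
        with open(groups_path, "w") as fh:
            for s in self.values.columns:
                fh.write(f"{s}\t{self.groups[s]}\n")


@dataclass(frozen=True)
class GenePrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0^2 scale.

    ``d0 = math.inf`` is the full-shrinkage sentinel.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is accepted as the explicit no-shrinkage limit
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0 (or inf), got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass
class DEGTable:
    """Per-gene DE calls plus summary counts and the thresholds used."""

    frame: pd.DataFrame  # columns: log2fc, t, p, fdr, direction
    n_up: int
    n_down: int
    p_max: float
    lfc_min: float
    use_fdr: bool

    def significant_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["direction"] != "ns"])

    def up_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["direction"] == "up"])

    def down_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["direction"] == "down"])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="gene", float_format="%.6g")

    def summary(self) -> dict:
        return {
            "n_genes": int(len(self.frame)),
            "n_up": self.n_up,
            "n_down": self.n_down,
            "p_max": self.p_max,
            "lfc_min": self.lfc_min,
            "use_fdr": self.use_fdr,
        }

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")


def gene_stats(profile: ExpressionProfile) -> pd.DataFrame:
    """Two-group sufficient statistics per gene.

    Returns a DataFrame with mean_case, mean_control, log2fc
    (case - control), pooled variance ``s2`` and its residual df ``d``
    (= n1 + n2 - 2), plus the group sizes.
    """
    case = profile.values[profile.samples(CASE)].to_numpy(float)
    ctrl = profile.values[profile.samples(CONTROL)].to_numpy(float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    ss1 = ((case - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((ctrl - m2[:, None]) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = (ss1 + ss2) / d
    return pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m2,
            "log2fc": m1 - m2,
            "s2": s2,
            "d": d,
            "n1": n1,
            "n2": n2,
        },
        index=profile.values.index,
    )


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so a
    positive solution exists for every y > 0.  The Newton step is taken on
    the asymptotically linear form x -> 1/trigamma(x), which converges from
    the standard starting value 0.5 + 1/y.
    """
    if y <= 0:
        raise ValueError(f"trigamma inverse needs y > 0, got {y}")
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float, min_genes: int = 10) -> GenePrior:
    """Fit (d0, s0^2) by moment matching on log s^2.

    Genes with s^2 = 0 are excluded from the fit; at least ``min_genes``
    positive variances are required.  If the excess variance of log s^2 over
    the chi-square sampling noise trigamma(d/2) is non-positive there is no
    gene-level dispersion to attribute and the full-shrinkage prior
    (d0 = inf) is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ExpressionError(
            "all gene variances are zero (constant matrix); cannot fit a variance prior"
        )
    if pos.size < min_genes:
        raise ExpressionError(
            f"need >= {min_genes} genes with positive variance, got {pos.size}"
        )
    e = np.log(pos) - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_bar = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        # no gene-level dispersion beyond chi-square noise: shrink fully to
        # the mean observed variance (unbiased under s^2 ~ s0^2 chi2_d / d)
        return GenePrior(d0=math.inf, s0_sq=float(pos.mean()))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    # E[e] = log s0^2 - digamma(d0/2) + log(d0/2) under s^2 ~ s0^2 F(d, d0)
    s0_sq = math.exp(e_bar + float(special.digamma(half_d0)) - math.log(half_d0))
    return GenePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(stats_frame: pd.DataFrame, prior: GenePrior) -> pd.DataFrame:
    """Moderated t statistic and two-sided p per gene.

    ``prior.d0 = 0`` is accepted as the no-shrinkage limit (ordinary pooled
    t); ``d0 = inf`` gives the normal-tail limit.  Genes whose posterior
    variance is exactly zero get p = NaN and are flagged, never called.
    """
    out = stats_frame.copy()
    d = out["d"].to_numpy(float)
    s2 = out["s2"].to_numpy(float)
    n1 = out["n1"].to_numpy(float)
    n2 = out["n2"].to_numpy(float)
    lfc = out["log2fc"].to_numpy(float)

    d0, s0 = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d

    se2 = s2_post * (1.0 / n1 + 1.0 / n2)
    degenerate = se2 <= 0
    if degenerate.any():
        log.warning(
            "%d genes with zero posterior variance excluded from DE calls",
            int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, lfc / np.sqrt(np.where(degenerate, 1.0, se2)))
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate, np.nan, p)
    out["t"] = t
    out["p"] = p
    out["df_total"] = df_total
    return out


def welch_t(stats_source: ExpressionProfile) -> pd.DataFrame:
    """Plain Welch two-sample t as a configuration alternative to the
    moderated statistic."""
    case = stats_source.values[stats_source.samples(CASE)].to_numpy(float)
    ctrl = stats_source.values[stats_source.samples(CONTROL)].to_numpy(float)
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    base = gene_stats(stats_source)
    base["t"] = t
    base["p"] = p
    return base


def call_degs(
    records: pd.DataFrame,
    p_max: float = P_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
    use_fdr: bool = False,
) -> DEGTable:
    """Call DE genes: p < p_max (strict) AND |log2fc| > lfc_min (strict).

    Genes with missing p (degenerate variance) are never significant.  BH
    FDR is always reported; with ``use_fdr`` it replaces p in the criterion.
    """
    frame = records.copy()
    p = frame["p"].to_numpy(float)
    ok = np.isfinite(p)
    fdr = np.full_like(p, np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    frame["fdr"] = fdr
    crit = fdr if use_fdr else p
    with np.errstate(invalid="ignore"):
        sig = ok & (crit < p_max) & (np.abs(frame["log2fc"].to_numpy(float)) > lfc_min)
    direction = np.where(
        sig & (frame["log2fc"].to_numpy(float) > 0),
        "up",
        np.where(sig, "down", "ns"),
    )
    frame["direction"] = direction
    cols = ["log2fc", "t", "p", "fdr", "direction"]
    return DEGTable(
        frame=frame[cols],
        n_up=int((direction == "up").sum()),
        n_down=int((direction == "down").sum()),
        p_max=p_max,
        lfc_min=lfc_min,
        use_fdr=use_fdr,
    )


def differential_expression(
    profile: ExpressionProfile,
    p_max: float = P_MAX_DEFAULT,
    lfc_min: float = LFC_MIN_DEFAULT,
    use_fdr: bool = False,
    test: str = "moderated",
) -> DEGTable:
    """End-to-end DE screen of one profile (``test``: moderated | welch)."""
    if test == "moderated":
        base = gene_stats(profile)
        prior = estimate_prior(base["s2"].to_numpy(), float(base["d"].iloc[0]))
        recs = moderated_t(base, prior)
    elif test == "welch":
        recs = welch_t(profile)
    else:
        raise ValueError(f"unknown test {test!r} (expected 'moderated' or 'welch')")
    return call_degs(recs, p_max=p_max, lfc_min=lfc_min, use_fdr=use_fdr)
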