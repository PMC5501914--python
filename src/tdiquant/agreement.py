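"""Observer-agreement statistics for paired peak-velocity measurements.

Implements the evaluation toolkit used to compare automated and manual
tracings: Bland-Altman bias and 95% limits of agreement, R-squared from
linear regression, leave-one-out expert consensus, beat matching between
raters, and an intra-/inter-operator variance decomposition of repeated
readings.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AgreementError


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary for one paired series.

    bias = mean(a - b); loa_half = 1.96 x sample SD (n-1) of the
    differences, so the 95% limits of agreement are bias +/- loa_half;
    r_squared comes from ordinary least-squares regression of a on b.
    """

    bias: float
    loa_half: float
    r_squared: float
    n: int
    means: np.ndarray               # per-pair (a+b)/2, for plotting
    diffs: np.ndarray               # per-pair a-b

    @property
    def loa_low(self) -> float:
        return self.bias - self.loa_half

    @property
    def loa_high(self) -> float:
        return self.bias + self.loa_half


def bland_altman(values_a: np.ndarray, values_b: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement between two measurement series."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("paired series must be equal-length vectors")
    if a.size < 3:
        raise AgreementError("insufficient pairs")
    d = a - b
    bias = float(d.mean())
    loa_half = float(1.96 * d.std(ddof=1))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r2 = 1.0 if np.allclose(d, d[0]) else 0.0
    else:
        r2 = float(stats.linregress(b, a).rvalue ** 2)
    return AgreementStats(bias=bias, loa_half=loa_half, r_squared=r2,
                          n=a.size, means=(a + b) / 2.0, diffs=d)


def consensus(measurements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat consensus (mean across raters) and leave-one-out consensus.

    ``measurements`` is raters x beats, NaN marking beats a rater missed.
    Returns ``(consensus, loo)`` where ``loo[r]`` is the per-beat mean over
    the other raters; beats missing any of those raters are NaN there.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise AgreementError("consensus undefined")
    full = np.nanmean(np.where(np.isnan(m), np.nan, m), axis=0)
    full = np.where(np.isnan(m).all(axis=0), np.nan, full)
    n_raters = m.shape[0]
    loo = np.empty_like(m)
    for r in range(n_raters):
        others = np.delete(m, r, axis=0)
        loo[r] = np.where(np.isnan(others).any(axis=0), np.nan, others.mean(axis=0))
    return full, loo


STRATUM_COLS = ["wall", "peak", "convention"]


def _stratum_components(df: pd.DataFrame) -> tuple[float, float] | None:
    """(intra_sd, inter_sd) for one stratum of the long repeats table."""
    wide = df.pivot_table(index=["beat", "rater"], columns="reading",
                          values="value_cm_s", aggfunc="first")
    if wide.shape[1] < 2:
        return None
    first, second = wide.iloc[:, 0], wide.iloc[:, 1]
    d = (first - second).dropna()
    if d.empty:
        return None
    # repeatability: SD of paired within-rater differences carries 2x the
    # per-reading variance, hence the 1/sqrt(2)
    intra_var = float(np.mean(d.values ** 2) / 2.0)

    rater_means = wide.mean(axis=1).unstack("rater")    # beats x raters
    rater_means = rater_means.dropna(axis=0, how="any")
    if rater_means.shape[0] < 1 or rater_means.shape[1] < 2:
        return None
    m = rater_means.shape[1]
    n_readings = wide.notna().sum(axis=1).mean()
    per_beat_var = rater_means.var(axis=1, ddof=1)      # across raters
    # a rater's per-beat mean still carries intra noise / n_readings; remove it
    inter_var = max(float(per_beat_var.mean()) - intra_var / max(n_readings, 1.0), 0.0)
    return float(np.sqrt(intra_var)), float(np.sqrt(inter_var))


def variance_components(repeats: pd.DataFrame) -> tuple[float, float, float]:
    """Split measurement variance into intra- and inter-operator parts.

    ``repeats`` is long-format with columns rater, reading (1|2), beat,
    value_cm_s and optionally the stratum columns wall/peak/convention.
    Per stratum, the intra-operator SD is the pooled SD of within-rater
    first-vs-repeat differences divided by sqrt(2); the inter-operator SD is
    the pooled across-rater SD of rater means with the residual intra
    contribution removed. Strata are averaged unweighted. Returns
    ``(intra_sd, inter_sd, intra_fraction)``.
    """
    df = repeats.copy()
    required = {"rater", "reading", "beat", "value_cm_s"}
    if not required.issubset(df.columns):
        raise AgreementError(f"repeats table needs columns {sorted(required)}")
    strata = [c for c in STRATUM_COLS if c in df.columns]
    groups = [g for _, g in df.groupby(strata)] if strata else [df]
    comps = [c for c in (_stratum_components(g) for g in groups) if c is not None]
    if not comps:
        raise AgreementError("intra-operator variance undefined")
    intra_sd = float(np.mean([c[0] for c in comps]))
    inter_sd = float(np.mean([c[1] for c in comps]))
    return intra_sd, inter_sd, intra_fraction(intra_sd, inter_sd)


def intra_fraction(intra_sd: float, inter_sd: float) -> float:
    """Share of total variance that is intra-operator:
    intra_sd^2 / (intra_sd^2 + inter_sd^2). NaN when both SDs are zero."""
    total = intra_sd ** 2 + inter_sd ** 2
    if total < 1e-24:
        return float("nan")                    # "no variance"
    return intra_sd ** 2 / total


def match_rater_beats(tables: dict[str, pd.DataFrame],
                      tol_s: float = 0.15) -> tuple[pd.DataFrame, dict[str, int]]:
    """Align per-rater beat tables by strip identity and peak time.

    Each table needs columns strip_id, t_s and value_cm_s. The rater with the
    most beats anchors the alignment; within each strip, every other rater's
    nearest unused beat within ``tol_s`` is matched to each anchor beat.
    Returns the aligned wide table (one column per rater, NaN = unmatched)
    and coverage counts: beats matched by every rater, and per-rater totals.
    """
    if len(tables) < 2:
        raise AgreementError("need at least two raters to match")
    anchor_name = max(sorted(tables), key=lambda k: len(tables[k]))
    anchor = tables[anchor_name].sort_values(["strip_id", "t_s"]).reset_index(drop=True)
    out = anchor[["strip_id", "t_s"]].copy()
    out[anchor_name] = anchor["value_cm_s"].to_numpy()
    for name, tab in tables.items():
        if name == anchor_name:
            continue
        col = np.full(len(anchor), np.nan)
        for strip_id, idx in anchor.groupby("strip_id").groups.items():
            cand = tab[tab["strip_id"] == strip_id]
            t_anchor = anchor.loc[idx, "t_s"].to_numpy()
            t_cand = cand["t_s"].to_numpy()
            v_cand = cand["value_cm_s"].to_numpy()
            pairs = sorted(((abs(ta - tc), i, j)
                            for i, ta in enumerate(t_anchor)
                            for j, tc in enumerate(t_cand)
                            if abs(ta - tc) <= tol_s),
                           key=lambda x: (x[0], x[1], x[2]))
            used_a: set[int] = set()
            used_c: set[int] = set()
            for _, i, j in pairs:
                if i in used_a or j in used_c:
                    continue
                used_a.add(i)
                used_c.add(j)
                col[list(idx)[i]] = v_cand[j]
        out[name] = col
    rater_cols = [c for c in out.columns if c not in ("strip_id", "t_s")]
    counts = {"n_anchor_beats": len(out),
              "n_matched_by_all": int(out[rater_cols].notna().all(axis=1).sum())}
    for name in rater_cols:
        counts[f"n_{name}"] = int(out[name].notna().sum())
    return out, counts


def agreement_report(aligned: pd.DataFrame, ref_col: str) -> pd.DataFrame:
    """Bland-Altman/R^2 summary of every rater column against ``ref_col``
    over beats both measured; one row per comparison."""
    rows = []
    rater_cols = [c for c in aligned.columns if c not in ("strip_id", "t_s")]
    for name in rater_cols:
        if name == ref_col:
            continue
        both = aligned[[name, ref_col]].dropna()
        if len(both) < 3:
            continue
        st = bland_altman(both[name].to_numpy(), both[ref_col].to_numpy())
        rows.append({"comparison": f"{name} vs {ref_col}", "bias": st.bias,
                     "loa_low": st.loa_low, "loa_high": st.loa_high,
                     "r_squared": st.r_squared, "n": st.n})
    return pd.DataFrame(rows)
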