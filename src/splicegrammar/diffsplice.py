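"""Per-event linear models of PSI on genotype, temperature and interaction.

Each event's PSI row is modelled by ordinary least squares as

    PSI ~ genotype + temperature + genotype:temperature

with genotype a two-level factor (reference: wild type) and temperature
categorical with the growth temperature (20 degC when present) as reference.
Per-term p-values come from partial F-tests on nested model pairs:

* genotype:     PSI ~ temperature        vs  PSI ~ genotype + temperature
* temperature:  PSI ~ genotype           vs  PSI ~ genotype + temperature
* interaction:  PSI ~ genotype + temp.   vs  full model

Missing PSIs are dropped per event (complete-case; no imputation).  BH
q-values are computed within term across events, and a 5% FDR is the default
significance threshold.  Effect sizes (delta PSI) are reported on the PSI
scale as mutant - wild-type mean PSI, per temperature and pooled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "EventTestResult",
    "fit_event_model",
    "fit_events",
    "bh_fdr",
    "call_significant",
    "label_lost_gained",
    "effect_size_by_category",
]

TERMS = ("genotype", "temperature", "interaction")
_ZERO_SSR_TOL = 1e-12


@dataclass
class EventTestResult:
    """Model coefficients, per-term p-values and delta-PSI for one event."""

    event_id: str
    n_obs: int
    coefficients: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    q_values: dict[str, float] = field(default_factory=dict)
    delta_psi: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    filtered: bool = False


class _DesignMatrices:
    """Design matrices for the nested OLS models, built once per design and
    reused across events (subset by the per-event complete-case mask)."""

    def __init__(self, design: pd.DataFrame,
                 reference_genotype: str | None = None,
                 reference_temperature=20,
                 logit: bool = False):
        design = design.copy()
        required = {"genotype", "temperature"}
        if not required <= set(design.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if design.index.has_duplicates:
            raise ValueError("duplicate sample_ids in design")
        genotypes = sorted(design["genotype"].unique())
        if len(genotypes) != 2:
            raise ValueError(f"need exactly 2 genotype levels, got {genotypes}")
        if reference_genotype is None:
            reference_genotype = "wt" if "wt" in genotypes else genotypes[0]
        self.reference_genotype = reference_genotype
        self.mutant_level = next(g for g in genotypes if g != reference_genotype)
        temps = sorted(design["temperature"].unique())
        if reference_temperature in temps:
            temps = [reference_temperature] + [t for t in temps if t != reference_temperature]
        self.temperatures = temps
        self.design = design
        self.logit = logit

        n = len(design)
        g = (design["genotype"] != reference_genotype).to_numpy(dtype=float)
        t_cols = [
            (design["temperature"] == t).to_numpy(dtype=float) for t in temps[1:]
        ]
        intercept = np.ones(n)
        self.names_full = (
            ["intercept", "genotype"]
            + [f"temp_{t}" for t in temps[1:]]
            + [f"genotype:temp_{t}" for t in temps[1:]]
        )
        self.X_full = np.column_stack([intercept, g] + t_cols + [g * c for c in t_cols])
        self.X_additive = np.column_stack([intercept, g] + t_cols)
        self.X_geno = np.column_stack([intercept, g])
        self.X_temp = np.column_stack([intercept] + t_cols) if t_cols else intercept[:, None]
        self.genotype_mask = g.astype(bool)


def _nested_f(full, restricted) -> float:
    """p-value of the partial F-test of ``restricted`` within ``full``."""
    if full.df_model <= restricted.df_model or full.df_resid <= 0:
        return float("nan")
    f, p, _ = full.compare_f_test(restricted)
    return float(p)


def _logit(y: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    y = np.clip(y, eps, 1 - eps)
    return np.log(y / (1 - y))


def fit_event_model(
    psi_row: Mapping[str, float] | pd.Series,
    design: pd.DataFrame | _DesignMatrices,
    min_obs: int = 3,
    event_id: str = "",
    logit: bool = False,
) -> EventTestResult:
    """Fit the per-event model on complete cases.

    ``min_obs`` is the minimum number of non-missing PSIs per genotype.
    Rows with zero residual variance or a rank-deficient full design are
    flagged degenerate with missing p-values.
    """
    dm = design if isinstance(design, _DesignMatrices) else _DesignMatrices(design, logit=logit)
    y_all = pd.Series(psi_row).reindex(dm.design.index).to_numpy(dtype=float)
    mask = ~np.isnan(y_all)
    result = EventTestResult(event_id=event_id, n_obs=int(mask.sum()))

    per_geno = [int((mask & (dm.genotype_mask == flag)).sum()) for flag in (False, True)]
    if min(per_geno) < min_obs:
        result.filtered = True
        return result

    y = y_all[mask]
    if dm.logit:
        y = _logit(y)
    Xf, Xa, Xg, Xt = (X[mask] for X in (dm.X_full, dm.X_additive, dm.X_geno, dm.X_temp))

    g = dm.genotype_mask[mask]
    temps_obs = dm.design["temperature"].to_numpy()[mask]
    y_raw = y_all[mask]
    deltas = {}
    for t in dm.temperatures:
        sel = temps_obs == t
        if (sel & g).any() and (sel & ~g).any():
            deltas[str(t)] = float(y_raw[sel & g].mean() - y_raw[sel & ~g].mean())
    deltas["pooled"] = float(y_raw[g].mean() - y_raw[~g].mean())
    result.delta_psi = deltas

    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        result.degenerate = True
        return result

    fit_full = sm.OLS(y, Xf).fit()
    if fit_full.ssr < _ZERO_SSR_TOL or fit_full.df_resid <= 0:
        result.degenerate = True
        result.coefficients = dict(zip(dm.names_full, map(float, fit_full.params)))
        return result
    fit_add = sm.OLS(y, Xa).fit()
    fit_geno = sm.OLS(y, Xg).fit()
    fit_temp = sm.OLS(y, Xt).fit()

    result.coefficients = dict(zip(dm.names_full, map(float, fit_full.params)))
    result.p_values = {
        "genotype": _nested_f(fit_add, fit_temp),
        "temperature": _nested_f(fit_add, fit_geno),
        "interaction": _nested_f(fit_full, fit_add),
    }
    return result


def fit_events(
    psi: pd.DataFrame,
    design: pd.DataFrame,
    min_obs: int = 3,
    alpha: float = 0.05,
    logit: bool = False,
) -> pd.DataFrame:
    """Fit every event (rows of ``psi``), BH-correct within term, and flag
    significance at ``alpha``; returns one row per event."""
    dm = _DesignMatrices(design, logit=logit)
    results = [
        fit_event_model(psi.loc[eid], dm, min_obs=min_obs, event_id=eid)
        for eid in psi.index
    ]
    rows = []
    for r in results:
        row = {
            "event_id": r.event_id,
            "n_obs": r.n_obs,
            "degenerate": r.degenerate,
            "filtered": r.filtered,
            "coef_genotype": r.coefficients.get("genotype", np.nan),
            "delta_psi_pooled": r.delta_psi.get("pooled", np.nan),
        }
        for t in dm.temperatures:
            row[f"delta_psi_{t}"] = r.delta_psi.get(str(t), np.nan)
        for term in TERMS:
            row[f"p_{term}"] = r.p_values.get(term, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("event_id")
    for term in TERMS:
        df[f"q_{term}"] = bh_fdr(df[f"p_{term}"].to_numpy())
    return call_significant(df, alpha=alpha)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are excluded and reinserted."""
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def call_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Add per-term significance flags and a partition label.

    Events with a significant interaction are labelled ``interaction``;
    otherwise the label records which main effects pass the FDR threshold.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = results.copy()
    for term in TERMS:
        df[f"sig_{term}"] = df[f"q_{term}"] < alpha
    def partition(row):
        if row["sig_interaction"]:
            return "interaction"
        if row["sig_genotype"] and row["sig_temperature"]:
            return "genotype+temperature"
        if row["sig_genotype"]:
            return "genotype"
        if row["sig_temperature"]:
            return "temperature"
        return "none"
    df["sig_class"] = df.apply(partition, axis=1)
    return df


def label_lost_gained(pair, delta_psi_inclusion: float):
    """Orient an AltPair's windows as (lost, gained) from the sign of the
    inclusion-form delta PSI (mutant - wild type).

    A negative delta means the inclusion-form site lost usage in the mutant
    (it is the sensitive site); the alternative site gained.  Also returns the
    signed distance of the usage shift: negative when usage shifted toward the
    upstream site.
    """
    if np.isnan(delta_psi_inclusion) or delta_psi_inclusion == 0:
        return None
    inc_up = pair.upstream_is_inclusion
    inclusion_lost = delta_psi_inclusion < 0
    lost_is_upstream = inc_up if inclusion_lost else not inc_up
    if lost_is_upstream:
        lost, gained = pair.upstream_window, pair.downstream_window
        shift = pair.distance  # usage moved downstream
    else:
        lost, gained = pair.downstream_window, pair.upstream_window
        shift = -pair.distance  # usage moved upstream
    return lost, gained, shift


def effect_size_by_category(
    categories: Sequence[str], abs_delta_psi: Sequence[float]
) -> pd.DataFrame:
    """n / median / quartile summary of |delta PSI| per category label."""
    df = pd.DataFrame({"category": categories, "abs_dpsi": abs_delta_psi})
    df = df.dropna()
    if df.empty:
        raise ValueError("no category / effect-size pairs to summarise")
    grouped = df.groupby("category")["abs_dpsi"]
    out = grouped.agg(
        n="count",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    return out.sort_index()
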