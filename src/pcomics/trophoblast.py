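"""Trophoblast developmental-state analysis.

Control trophoblasts at term segregate into a juvenile and an adult
population along RNA-velocity latent time; preeclamptic (PE) cells sit
between them. This module fits the two-component Gaussian mixture
(diagnostic), classifies immature cells by the fixed published
thresholds (CytoTRACE < 0.2 and latent time < 0.4), tests the per-donor
immature frequency between phenotypes, and computes mitosis aging rates
(mitotic age / gestational week) with per-lineage rank-sum tests.

Latent time, CytoTRACE scores and mitotic ages are consumed as inputs;
inferring them is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

CYTO_THRESHOLD = 0.2
LATENT_THRESHOLD = 0.4


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture, components ascending by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    responsibility: np.ndarray  # (n, 2) posterior of each component
    log_likelihood: float
    degenerate: bool = False


def fit_bimodal_latent(
    latent_times: np.ndarray,
    seed: int = 0,
    max_restarts: int = 10,
    min_sd: float = 1e-4,
) -> MixtureFit:
    """EM fit of a two-component normal mixture to latent times.

    Components are reported in ascending mean order. A fit whose
    component scale collapses below ``min_sd`` is retried with a
    reseeded k-means++ initialization (up to ``max_restarts``); an
    all-identical input is returned as a flagged degenerate fit.
    """
    x = np.asarray(latent_times, dtype=float).reshape(-1, 1)
    if len(x) < 50:
        raise ValueError("need >=50 latent-time values for a stable mixture fit")
    if np.ptp(x) == 0:
        c = float(x[0, 0])
        return MixtureFit(
            means=np.array([c, c]),
            sds=np.array([0.0, 0.0]),
            weights=np.array([0.5, 0.5]),
            responsibility=np.full((len(x), 2), 0.5),
            log_likelihood=float("nan"),
            degenerate=True,
        )
    last_err = None
    for r in range(max_restarts):
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            tol=1e-8,
            max_iter=500,
            init_params="k-means++",
            random_state=seed + r,
            reg_covar=1e-10,
        )
        gm.fit(x)
        sds = np.sqrt(gm.covariances_.reshape(2))
        if np.all(sds > min_sd):
            order = np.argsort(gm.means_.ravel())
            resp = gm.predict_proba(x)[:, order]
            return MixtureFit(
                means=gm.means_.ravel()[order],
                sds=sds[order],
                weights=gm.weights_[order],
                responsibility=resp,
                log_likelihood=float(gm.score(x) * len(x)),
            )
        last_err = f"component sd collapsed below {min_sd} (restart {r})"
    raise RuntimeError(f"EM degenerate after {max_restarts} restarts: {last_err}")


def classify_immature(
    cells: pd.DataFrame,
    cyto_thr: float = CYTO_THRESHOLD,
    latent_thr: float = LATENT_THRESHOLD,
) -> pd.Series:
    """Immature iff cytotrace < cyto_thr AND latent_time < latent_thr.

    Both inequalities are strict, as published. Cells missing either
    score are left unclassified (NA).
    """
    cyto = cells["cytotrace"]
    latent = cells["latent_time"]
    flag = (cyto < cyto_thr) & (latent < latent_thr)
    flag = flag.astype("boolean")
    flag[cyto.isna() | latent.isna()] = pd.NA
    return flag


def immature_frequency_test(
    cells: pd.DataFrame,
    cyto_thr: float = CYTO_THRESHOLD,
    latent_thr: float = LATENT_THRESHOLD,
) -> dict:
    """Per-donor immature-trophoblast fractions and Welch t-test PE vs control.

    fraction = immature trophoblasts / all trophoblasts per donor. The
    raw two-sided p is reported; with fewer than 2 donors in a phenotype
    the p-value is NaN and only fractions are returned.
    """
    flags = classify_immature(cells, cyto_thr, latent_thr)
    df = pd.DataFrame(
        {
            "donor": cells["donor"],
            "phenotype": cells["phenotype"],
            "immature": flags.astype(float),
        }
    ).dropna()
    fractions = (
        df.groupby(["phenotype", "donor"])["immature"].mean().rename("fraction").reset_index()
    )
    pe = fractions.loc[fractions["phenotype"] == "PE", "fraction"].to_numpy()
    ctrl = fractions.loc[fractions["phenotype"] == "control", "fraction"].to_numpy()
    if len(pe) >= 2 and len(ctrl) >= 2:
        t = stats.ttest_ind(pe, ctrl, equal_var=False)
        p = float(t.pvalue)
        statistic = float(t.statistic)
        if np.isnan(p) and pe.mean() == ctrl.mean():
            p, statistic = 1.0, 0.0  # zero variance in both groups, no difference
    else:
        p, statistic = float("nan"), float("nan")
    return {
        "fractions": fractions,
        "mean_diff": float(pe.mean() - ctrl.mean()) if len(pe) and len(ctrl) else float("nan"),
        "t_statistic": statistic,
        "p_value": p,
    }


def mitosis_aging_rate(cells: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-cell aging rate and per-lineage Wilcoxon rank-sum PE vs control.

    rate = mitotic_age / gestational_week; the two-sided rank-sum
    (Mann-Whitney) raw p is reported per lineage.
    """
    gw = cells["gestational_week"]
    if (gw <= 0).any():
        raise ValueError("gestational_week must be > 0")
    rate = (cells["mitotic_age"] / gw).rename("aging_rate")
    rows = []
    for lineage, sub in cells.assign(rate=rate).groupby("lineage", sort=True):
        pe = sub.loc[sub["phenotype"] == "PE", "rate"].to_numpy()
        ctrl = sub.loc[sub["phenotype"] == "control", "rate"].to_numpy()
        if len(pe) and len(ctrl):
            res = stats.mannwhitneyu(pe, ctrl, alternative="two-sided", method="asymptotic")
            p = float(res.pvalue)
        else:
            p = float("nan")
        rows.append(
            (
                lineage,
                float(np.median(pe)) if len(pe) else float("nan"),
                float(np.median(ctrl)) if len(ctrl) else float("nan"),
                p,
            )
        )
    table = pd.DataFrame(rows, columns=["lineage", "median_rate_PE", "median_rate_control", "p_value"])
    return rate, table


def proliferation_score(cells: pd.DataFrame) -> pd.Series:
    """Single proliferation scalar: G2M score + S score."""
    return (cells["g2m_score"] + cells["s_score"]).rename("proliferation_score")
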