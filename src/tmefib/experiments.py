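"""Reproducible study-scale experiments built from the library pieces.

These functions run the package's own methods on synthetic inputs at desk
scale and return the quantities of scientific interest: phenotype recovery
by HCPC from measured fiber morphometrics, the fiber-metric/TIL correlation
structure, mixed-model effect recovery and null calibration, and
Monte-Carlo recovery of the planted TLS odds ratio.  Both the test suite
and the acceptance script call into here so the two always measure the
same computation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.metrics import adjusted_rand_score

from .clustering import cluster_til_comparison, fit_pca, hcpc
from .morphometrics import METRIC_NAMES, compute_metrics
from .stats import fit_random_intercept_lmm, log_transform, spearman_matrix
from .synth import (
    PHENOTYPE_A,
    PHENOTYPE_B,
    CohortGenParams,
    generate_cohort,
    generate_fiber_network,
)

__all__ = [
    "phenotype_region_table",
    "phenotype_recovery",
    "lmm_effect_recovery",
    "lmm_null_calibration",
    "planted_or_recovery",
]

#: the directional fingerprints the two phenotypes are designed to plant
CLUSTER1_SIGNS = {
    "avg_fiber_length": "up",
    "total_length": "up",
    "lacunarity": "up",
    "alignment": "down",
    "density": "down",
}
SPEARMAN_SIGNS = {
    "lacunarity": 1,
    "avg_fiber_length": 1,
    "hyphal_growth_unit": -1,
    "hdm": -1,
}


def phenotype_region_table(
    n_per_arm: int = 32,
    size: int = 256,
    seed: int = 0,
    til_params: CohortGenParams | None = None,
) -> pd.DataFrame:
    """Measure the 13 morphometrics on generated two-phenotype regions.

    Each stromal region is an independent square field drawn from phenotype
    A or B; a TIL count is attached per region from the gamma-Poisson count
    model with the phenotype effect (``til_beta_phenotypeA``), emulating the
    tumor each region surrounds.  Returns one row per region with metric
    columns, ``phenotype`` and ``til_count``.
    """
    p = til_params or CohortGenParams()
    rng = np.random.default_rng(seed)
    rows = []
    for arm, params in (("A", PHENOTYPE_A), ("B", PHENOTYPE_B)):
        for i in range(n_per_arm):
            s = int(rng.integers(2**31 - 1))
            net = generate_fiber_network(params, shape=(size, size), seed=s)
            intensity = gaussian_filter(net.mask.astype(float), 2.0)
            fm = compute_metrics(net.mask, intensity=intensity, pixel_size=1.0)
            log_mu = (
                p.til_beta0
                + p.til_beta_phenotypeA * (arm == "A")
                + rng.normal(0.0, p.lesion_sd)
            )
            gam = rng.gamma(1.0 / p.til_dispersion, p.til_dispersion)
            til = int(rng.poisson(math.exp(log_mu) * gam))
            row = fm.as_dict()
            row["phenotype"] = arm
            row["til_count"] = til
            rows.append(row)
    return pd.DataFrame(rows)


def phenotype_recovery(
    regions: pd.DataFrame, k: int = 3, retain: int = 7
) -> dict:
    """HCPC on the measured morphometrics; compare clusters to phenotypes.

    Returns the adjusted Rand index between the two largest clusters and
    the true phenotype labels (restricted to samples in those clusters),
    the characterization direction pattern of the phenotype-A-dominated
    cluster, the Spearman signs of the four sentinel metrics against TIL
    counts, and the fitted cluster model.
    """
    metrics = regions[list(METRIC_NAMES)].copy()
    model = fit_pca(metrics, standardize=True)
    fcm = hcpc(model, k=k, retain=retain, metrics=metrics)
    labels = fcm.labels

    sizes = labels.value_counts()
    top2 = list(sizes.index[:2])
    in_top = labels.isin(top2)
    ari = adjusted_rand_score(
        regions.loc[in_top.values, "phenotype"], labels[in_top]
    )

    # phenotype-A-dominated cluster: check characterization directions
    a_frac = {
        c: (regions.loc[(labels == c).values, "phenotype"] == "A").mean() for c in top2
    }
    a_cluster = max(a_frac, key=a_frac.get)
    ch = fcm.characterization
    directions = {
        m: ch[(ch.metric == m) & (ch.cluster == a_cluster)].direction.iloc[0]
        for m in CLUSTER1_SIGNS
    }
    signs_ok = {m: directions[m] == want for m, want in CLUSTER1_SIGNS.items()}

    rho, pval, _ = spearman_matrix(
        regions[list(SPEARMAN_SIGNS)], regions["til_count"].rename("til")
    )
    spearman = {m: float(rho.loc[m, "til"]) for m in SPEARMAN_SIGNS}
    spearman_ok = {
        m: np.sign(spearman[m]) == want for m, want in SPEARMAN_SIGNS.items()
    }
    til_table = cluster_til_comparison(regions["til_count"], labels)
    return {
        "ari": float(ari),
        "a_cluster": int(a_cluster),
        "directions": directions,
        "directions_ok": signs_ok,
        "spearman": spearman,
        "spearman_ok": spearman_ok,
        "model": fcm,
        "til_comparison": til_table,
    }


def _stage_design(tumors: pd.DataFrame):
    sub = tumors[tumors.proximity == "proximal"]
    y = log_transform(sub.til_count.to_numpy())
    X = pd.DataFrame(
        {
            "const": 1.0,
            "primary": (sub.nearest_tls_stage == "primary").astype(float),
        },
        index=sub.index,
    )
    return y, X, sub.lesion_id.to_numpy()


def lmm_effect_recovery(
    n_lesions: int = 200,
    seed: int = 11,
    params: CohortGenParams | None = None,
    n_rep: int = 1,
) -> dict:
    """Fit the stage effect on simulated cohorts; compare to the truth.

    With ``n_rep`` > 1 the reported estimate is the mean fitted effect over
    independent cohorts (a lower-noise Monte-Carlo estimate of what the
    model recovers).
    """
    p = (params or CohortGenParams()).with_(n_lesions=n_lesions)
    ests, ses, ps, n_groups = [], [], [], 0
    for r in range(n_rep):
        _, _, tumors = generate_cohort(p, seed=seed + r)
        y, X, g = _stage_design(tumors)
        fit = fit_random_intercept_lmm(y, X, g, group_name="lesion", transform="log")
        ests.append(float(fit.params["primary"]))
        ses.append(float(fit.bse["primary"]))
        ps.append(float(fit.pvalues["primary"]))
        n_groups = fit.n_groups
    return {
        "estimate": float(np.mean(ests)),
        "truth": p.til_beta_primary,
        "se": float(np.mean(ses)) / math.sqrt(n_rep),
        "p": float(ps[0]),
        "n_groups": n_groups,
        "n_rep": n_rep,
    }


def lmm_null_calibration(
    n_sim: int = 1000, n_lesions: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Wald rejection rate of the stage effect under the generator's null."""
    null = CohortGenParams(n_lesions=n_lesions, til_beta_primary=0.0)
    rej = 0
    for s in range(n_sim):
        _, _, tumors = generate_cohort(null, seed=seed + 20000 + s)
        y, X, g = _stage_design(tumors)
        fit = fit_random_intercept_lmm(y, X, g)
        rej += fit.pvalues["primary"] < alpha
    return {"rejection_rate": rej / n_sim, "n_sim": n_sim, "alpha": alpha}


def planted_or_recovery(n_lesions: int = 10000, seed: int = 5) -> dict:
    """Monte-Carlo recovery of the planted nodular->TLS odds ratio."""
    p = CohortGenParams(n_lesions=n_lesions)
    lesions, _, _ = generate_cohort(p, seed=seed)
    a = int(((lesions.nodular == 1) & (lesions.any_tls == 1)).sum())
    b = int(((lesions.nodular == 1) & (lesions.any_tls == 0)).sum())
    c = int(((lesions.nodular == 0) & (lesions.any_tls == 1)).sum())
    d = int(((lesions.nodular == 0) & (lesions.any_tls == 0)).sum())
    emp = (a * d) / (b * c)
    return {
        "empirical_or": float(emp),
        "planted_or": float(np.exp(p.tls_logit_nodular)),
        "n": n_lesions,
    }
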