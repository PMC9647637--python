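"""Synthetic cohort generation with planted statistical structure.

Lesion covariates are independent Bernoulli draws at the study frequencies;
TLS presence follows a logistic model in the nodular flag; TLS maturation
stage (primary vs aggregate) is Bernoulli per lesion; per-tumor TIL counts
follow a gamma-Poisson (negative-binomial-like) count model whose log mean
is

    til_beta0 + til_beta_primary * [proximal to primary TLS]
              + til_beta_phenotypeA * [stromal phenotype A]
              + u_lesion,     u_lesion ~ Normal(0, lesion_sd^2)

and tumor killing is Bernoulli with logit linear in log TIL count.  Every
planted quantity is kept in the returned tables, so parameter-recovery tests
can compare fitted against generating values.

Defaults mirror the study conditions: 30 lesions, covariate frequencies from
the published cohort, nodular -> TLS log-odds ln(10.29), baseline TIL level
at the aggregate-proximal group mean, primary-stage effect 0.7 on the log
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["CohortGenParams", "generate_cohort"]


def _logit(p):
    return math.log(p / (1 - p))


@dataclass(frozen=True)
class CohortGenParams:
    n_lesions: int = 30
    p_nodular: float = 25 / 30
    p_superficial: float = 10 / 30
    p_infiltrative: float = 5 / 30
    p_ulceration: float = 21 / 30
    tls_logit_intercept: float = _logit(0.2)  # TLS rate in non-nodular lesions
    tls_logit_nodular: float = math.log(10.29)
    stage_logit: float = _logit(11 / 19)  # P(primary | TLS)
    til_beta0: float = math.log(17.6)  # aggregate-proximal baseline
    til_beta_primary: float = 0.7
    til_beta_phenotypeA: float = 0.8
    lesion_sd: float = 0.5
    til_dispersion: float = 0.6  # gamma-Poisson overdispersion
    killing_logit_intercept: float = -3.0
    killing_logit_slope: float = 1.0  # per log TIL
    p_phenotype_a: float = 0.5
    p_mucin: float = 0.2
    p_amyloid: float = 0.15
    n_tumors_mean: float = 6.0  # Poisson mean of extra tumors per lesion
    seed: int = 0

    def __post_init__(self):
        for name in ("p_nodular", "p_superficial", "p_infiltrative", "p_ulceration",
                     "p_phenotype_a", "p_mucin", "p_amyloid"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.lesion_sd < 0:
            raise ValueError("lesion_sd must be nonnegative")
        if self.til_dispersion <= 0:
            raise ValueError("til_dispersion must be positive")
        if self.n_lesions < 2:
            raise ValueError("cohort needs at least 2 lesions (mixed model untestable)")

    def with_(self, **kw) -> "CohortGenParams":
        return replace(self, **kw)


_BODY_SITES = ("head and neck", "trunk", "extremity")
_BODY_P = (16 / 30, 11 / 30, 3 / 30)


def generate_cohort(params: CohortGenParams, seed: int | None = None):
    """Generate lesion, TLS and tumor tables with full ground truth.

    Returns ``(lesions, tls, tumors)`` DataFrames.  Deterministic for a fixed
    seed (``seed`` overrides ``params.seed``).  Each lesion carries a latent
    random intercept; each tumor a phenotype label, its true log-mean and the
    realized TIL count; TLS rows carry stage and planted T/B compositions.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_lesions

    nodular = rng.random(n) < params.p_nodular
    superficial = rng.random(n) < params.p_superficial
    infiltrative = rng.random(n) < params.p_infiltrative
    ulceration = rng.random(n) < params.p_ulceration
    body_site = rng.choice(_BODY_SITES, size=n, p=_BODY_P)
    age = np.clip(rng.normal(67.9, 11.0, n), 30, 95).round()
    gender = rng.choice(["M", "F"], size=n, p=[19 / 29, 10 / 29])

    logit_tls = params.tls_logit_intercept + params.tls_logit_nodular * nodular
    has_tls = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_tls))
    intercepts = rng.normal(0.0, params.lesion_sd, n)

    lesion_rows, tls_rows, tumor_rows = [], [], []
    p_primary = 1.0 / (1.0 + math.exp(-params.stage_logit))
    for i in range(n):
        lesion_id = f"SL{i + 1:03d}"
        n_tls = int(rng.poisson(1.2) + 1) if has_tls[i] else 0
        stages = []
        for j in range(n_tls):
            stage = "primary" if rng.random() < p_primary else "aggregate"
            stages.append(stage)
            # planted TLS composition: primary TLS are bigger and B-richer
            if stage == "primary":
                area = rng.gamma(4, 0.04)  # mm^2, ~0.16
                b_frac = rng.beta(4, 60)  # ~0.06
                total = int(rng.gamma(4, 300))
            else:
                area = rng.gamma(3, 0.02)  # ~0.06
                b_frac = rng.beta(2, 160)  # ~0.012
                total = int(rng.gamma(3, 180))
            b = int(round(total * b_frac))
            tls_rows.append(
                {
                    "tls_id": f"{lesion_id}_TLS{j + 1}",
                    "lesion_id": lesion_id,
                    "stage": stage,
                    "true_area_mm2": area,
                    "true_t_count": total - b,
                    "true_b_count": b,
                }
            )
        n_tumors = int(rng.poisson(params.n_tumors_mean)) + 1
        for k in range(n_tumors):
            if n_tls:
                tls_j = int(rng.integers(n_tls))
                proximity = "proximal" if rng.random() < 0.8 else "distal"
                stage = stages[tls_j]
                tls_id = f"{lesion_id}_TLS{tls_j + 1}"
            else:
                proximity, stage, tls_id = "control", None, None
            phen_a = rng.random() < params.p_phenotype_a
            is_primary_prox = proximity == "proximal" and stage == "primary"
            log_mu = (
                params.til_beta0
                + params.til_beta_primary * is_primary_prox
                + params.til_beta_phenotypeA * phen_a
                + intercepts[i]
            )
            shape = 1.0 / params.til_dispersion
            gam = rng.gamma(shape, params.til_dispersion)
            til = int(rng.poisson(math.exp(log_mu) * gam))
            logit_kill = (
                params.killing_logit_intercept
                + params.killing_logit_slope * math.log(til + 0.5)
            )
            killing = rng.random() < 1.0 / (1.0 + math.exp(-logit_kill))
            tumor_rows.append(
                {
                    "tumor_id": f"{lesion_id}_T{k + 1}",
                    "lesion_id": lesion_id,
                    "tls_id": tls_id,
                    "proximity": proximity,
                    "nearest_tls_stage": stage,
                    "phenotype": "A" if phen_a else "B",
                    "true_log_mu": log_mu,
                    "til_count": til,
                    "killing": killing,
                    "mucin": bool(rng.random() < params.p_mucin),
                    "amyloid": bool(rng.random() < params.p_amyloid),
                }
            )
        lesion_rows.append(
            {
                "lesion_id": lesion_id,
                "age": age[i],
                "gender": gender[i],
                "body_site": body_site[i],
                "nodular": int(nodular[i]),
                "superficial": int(superficial[i]),
                "infiltrative": int(infiltrative[i]),
                "ulceration": int(ulceration[i]),
                "any_tls": int(has_tls[i]),
                "primary_tls": int(any(s == "primary" for s in stages)),
                "n_tls": n_tls,
                "true_intercept": intercepts[i],
            }
        )
    return (
        pd.DataFrame(lesion_rows),
        pd.DataFrame(tls_rows),
        pd.DataFrame(tumor_rows),
    )
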