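"""The two simulation benchmarks for comparing association measures.

``pair_benchmark`` sweeps bivariate-normal pairs across the correlation
range and computes, per pair, the Pearson correlation, bicor, the
MI-based adjacencies (symmetric uncertainty and both universal versions,
Miller-Madow estimator with sqrt(m) equal-width bins) and the cor-MI
prediction of AUV2 from |cor|.  Its summary statistics quantify (a) how
tightly AUV1 and AUV2 agree in rank order, (b) how accurately the cor-MI
map predicts the observed AUV2, and (c) how close bicor is to the Pearson
correlation under normality.

``module_benchmark`` runs the module-recovery comparison: module-structured
expression data with linear and quadratic gene-gene relationships is
generated repeatedly, every requested measure's pipeline (identical
clustering settings) is applied, and the Rand index against the simulated
truth is averaged over seeds.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .correlation import bicor as _bicor
from .correlation import pearson_cor
from .information import (
    default_n_bins,
    entropy,
    equal_width_discretize,
    mutual_information,
)
from .mi_adjacency import cor_mi_params, f_cor_mi
from .modules import modules_pipeline, rand_index
from .simulate import ModuleSimConfig, PairSimConfig, simulate_module_data, simulate_pairs

PAIR_MEASURE_KEYS = ("cor", "bicor", "asu", "auv1", "auv2", "predicted_auv2")


def pair_benchmark(n_pairs: int = 2000, m: int = 1000, seed: int = 0,
                   estimator: str = "miller_madow") -> dict:
    """Correlation-vs-MI measures on the bivariate-normal pair sweep.

    Returns a dict with per-pair arrays (keys of PAIR_MEASURE_KEYS) and the
    summary statistics ``spearman_auv1_auv2``, ``prediction_mae``,
    ``prediction_pearson`` and ``bicor_pearson_mean_absdiff``.
    """
    pairs = simulate_pairs(PairSimConfig(n_pairs=n_pairs, m=m, seed=seed))
    n_bins = default_n_bins(m)
    params = cor_mi_params(m)
    out = {k: np.empty(len(pairs)) for k in PAIR_MEASURE_KEYS}
    for idx, (x, y, _r) in enumerate(pairs):
        dx = equal_width_discretize(x, n_bins).bins
        dy = equal_width_discretize(y, n_bins).bins
        hx = entropy(dx, estimator).value
        hy = entropy(dy, estimator).value
        mi = mutual_information(dx, dy, estimator)
        asu = min(2.0 * mi / (hx + hy), 1.0)
        out["asu"][idx] = asu
        out["auv1"][idx] = asu / (2.0 - asu)
        out["auv2"][idx] = min(mi / max(hx, hy), 1.0)
        c = pearson_cor(x, y)
        out["cor"][idx] = c
        out["bicor"][idx] = _bicor(x, y)
        out["predicted_auv2"][idx] = f_cor_mi(abs(c), params)
    out["spearman_auv1_auv2"] = float(
        stats.spearmanr(out["auv1"], out["auv2"]).statistic
    )
    err = out["predicted_auv2"] - out["auv2"]
    out["prediction_mae"] = float(np.abs(err).mean())
    out["prediction_pearson"] = float(
        stats.pearsonr(out["predicted_auv2"], out["auv2"]).statistic
    )
    out["bicor_pearson_mean_absdiff"] = float(
        np.abs(out["bicor"] - out["cor"]).mean()
    )
    out["n_pairs"] = len(pairs)
    out["m"] = m
    return out


DEFAULT_BENCHMARK_MEASURES = ("bicor-signed", "bicor-tom", "auv2", "poly", "spline")


def module_benchmark(measures=DEFAULT_BENCHMARK_MEASURES, n_seeds: int = 10,
                     quadratic_fraction: float = 0.5, seed: int = 0,
                     config: ModuleSimConfig | None = None) -> dict:
    """Mean module-recovery Rand index per measure over repeated simulations.

    Returns {"mean_rand": {measure: float}, "per_seed": {measure: [floats]},
    "n_seeds": int, "config": ModuleSimConfig-of-last-run}.
    """
    template = config if config is not None else ModuleSimConfig()
    per_seed: dict[str, list[float]] = {meas: [] for meas in measures}
    for rep in range(n_seeds):
        cfg = ModuleSimConfig(
            n_genes=template.n_genes, m=template.m,
            n_modules=template.n_modules, module_sizes=template.module_sizes,
            quadratic_fraction=quadratic_fraction,
            n_quadratic_modules=template.n_quadratic_modules,
            strength=template.strength, noise_sd=template.noise_sd,
            sign_flip_prob=template.sign_flip_prob,
            seed=(seed * 7919 + rep) % (2**31 - 1),
        )
        expr, truth = simulate_module_data(cfg)
        for meas in measures:
            labels = modules_pipeline(expr, measure=meas)
            per_seed[meas].append(rand_index(truth, labels))
    return {
        "mean_rand": {meas: float(np.mean(v)) for meas, v in per_seed.items()},
        "per_seed": per_seed,
        "n_seeds": n_seeds,
        "n_genes": template.n_genes,
        "m": template.m,
    }
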