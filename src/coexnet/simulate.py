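"""Synthetic expression data for benchmarking association measures.

Two generators are provided:

* ``simulate_pairs`` draws pairs (x, y) from a bivariate normal with a
  prescribed correlation r: x ~ N(0, 1)^m and y = r x + sqrt(1 - r^2) eta
  with eta independent standard normal.  The default sweep covers 2000
  target correlations equally spaced across (-0.999, 0.999) at m = 1000,
  which is the design used to study how MI-based adjacencies relate to the
  correlation and how well the cor-MI map predicts AUV2.

* ``simulate_module_data`` builds a module-structured expression matrix:
  each module has a latent seed profile e ~ N(0, 1)^m; member genes are
  either linear (a x e + noise) or quadratic (a x (e - mean(e))^2 + noise)
  in the seed, with coupling a = +-strength (positive by default;
  ``sign_flip_prob`` controls the chance of a negative coupling, under
  which signed networks see the flipped genes as disconnected).  Two of the
  three modules contain a mix of linear and quadratic members (so
  linear-only measures see near-zero correlation between the two kinds,
  E[e (e^2 - 1)] = 0 for symmetric e), the third is purely linear, and the
  remaining genes are unstructured background noise.  Defaults: 200 genes
  across 200 samples as three modules of 60 plus 20 background genes, a
  quadratic fraction of 0.5 within the two nonlinear modules, unit signal
  strength and noise sd 0.5.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validation import ValidationError


@dataclass
class PairSimConfig:
    """Bivariate-normal pair sweep configuration."""

    n_pairs: int = 2000
    m: int = 1000
    correlation_grid: np.ndarray | None = None
    seed: int = 0

    def resolve_grid(self) -> np.ndarray:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.m < 20:
            raise ValidationError("pair simulation requires m >= 20")
        if self.correlation_grid is None:
            grid = np.linspace(-0.999, 0.999, self.n_pairs)
        else:
            grid = np.asarray(self.correlation_grid, dtype=float).ravel()
        if (np.abs(grid) >= 1).any():
            raise ValidationError("target correlations must lie in (-1, 1)")
        return grid


def simulate_pairs(config: PairSimConfig | None = None, **kwargs):
    """Generate bivariate-normal pairs with prescribed correlations.

    Returns a list of (x, y, target_r) tuples, one per grid value.
    """
    if config is None:
        config = PairSimConfig(**kwargs)
    grid = config.resolve_grid()
    rng = np.random.default_rng(config.seed)
    out = []
    for r in grid:
        x = rng.standard_normal(config.m)
        eta = rng.standard_normal(config.m)
        y = r * x + np.sqrt(1.0 - r * r) * eta
        out.append((x, y, float(r)))
    return out


@dataclass
class ModuleSimConfig:
    """Module-structured expression simulation configuration."""

    n_genes: int = 200
    m: int = 200
    n_modules: int = 3
    module_sizes: tuple = field(default=None)  # default: equal sizes of 60
    quadratic_fraction: float = 0.5
    n_quadratic_modules: int = 2
    strength: float = 1.0
    noise_sd: float = 0.5
    sign_flip_prob: float = 0.0
    seed: int = 0

    def resolve_sizes(self) -> list[int]:
        if self.n_modules < 1:
            raise ValidationError("need at least one module")
        if self.module_sizes is None:
            # 90% of genes split evenly across modules, remainder background
            # (200 genes / 3 modules -> 3 x 60 + 20 background)
            sizes = [int(0.9 * self.n_genes) // self.n_modules] * self.n_modules
        else:
            sizes = [int(s) for s in self.module_sizes]
        if len(sizes) != self.n_modules:
            raise ValidationError("module_sizes length must equal n_modules")
        if sum(sizes) > self.n_genes:
            raise ValidationError("module sizes exceed the number of genes")
        if not 0.0 <= self.quadratic_fraction <= 1.0:
            raise ValidationError("quadratic_fraction must lie in [0, 1]")
        if not 0 <= self.n_quadratic_modules <= self.n_modules:
            raise ValidationError("n_quadratic_modules out of range")
        if self.m < 3:
            raise ValidationError("need m >= 3 samples")
        return sizes


def simulate_module_data(config: ModuleSimConfig | None = None, **kwargs):
    """Generate a module-structured expression matrix and its true partition.

    Returns (expr, truth): a genes x samples DataFrame and a pd.Series of
    true module labels (1..n_modules, 0 for background genes).
    """
    if config is None:
        config = ModuleSimConfig(**kwargs)
    sizes = config.resolve_sizes()
    rng = np.random.default_rng(config.seed)
    rows = []
    labels = []
    gene = 0
    for mod_idx, size in enumerate(sizes, start=1):
        e = rng.standard_normal(config.m)
        quad = (e - e.mean()) ** 2
        nonlinear = mod_idx <= config.n_quadratic_modules
        n_quad = int(round(config.quadratic_fraction * size)) if nonlinear else 0
        for g in range(size):
            flip = rng.random() < config.sign_flip_prob
            a = config.strength * (-1.0 if flip else 1.0)
            base = quad if g < n_quad else e
            rows.append(a * base + config.noise_sd * rng.standard_normal(config.m))
            labels.append(mod_idx)
            gene += 1
    for _ in range(config.n_genes - sum(sizes)):
        rows.append(rng.standard_normal(config.m))
        labels.append(0)
        gene += 1
    ids = [f"g{i + 1}" for i in range(config.n_genes)]
    expr = pd.DataFrame(
        np.vstack(rows), index=ids,
        columns=[f"s{j + 1}" for j in range(config.m)],
    )
    truth = pd.Series(labels, index=ids, name="module", dtype=int)
    return expr, truth


def sample_size_sweep(m_values, measures, config: ModuleSimConfig | None = None,
                      n_replicates: int = 3, seed: int = 0,
                      cut_height="auto", min_module_size: int = 20) -> pd.DataFrame:
    """Module-recovery Rand index per sample size, measure and replicate.

    For each m in ``m_values`` and each replicate, one module-structured
    data set is simulated (fresh seed derived from ``seed``) and every
    measure's pipeline is run on the same data with identical clustering
    settings.  Returns a tidy DataFrame (m, measure, replicate, rand_index).
    """
    from .modules import modules_pipeline, rand_index

    template = config if config is not None else ModuleSimConfig()
    records = []
    for mi_m, m in enumerate(m_values):
        for rep in range(n_replicates):
            cfg = ModuleSimConfig(
                n_genes=template.n_genes, m=int(m),
                n_modules=template.n_modules,
                module_sizes=template.module_sizes,
                quadratic_fraction=template.quadratic_fraction,
                n_quadratic_modules=template.n_quadratic_modules,
                strength=template.strength, noise_sd=template.noise_sd,
                sign_flip_prob=template.sign_flip_prob,
                seed=(seed * 100003 + mi_m * 1009 + rep) % (2**31 - 1),
            )
            expr, truth = simulate_module_data(cfg)
            for measure in measures:
                labels = modules_pipeline(
                    expr, measure=measure, cut_height=cut_height,
                    min_module_size=min_module_size,
                )
                records.append(
                    {
                        "m": int(m),
                        "measure": measure,
                        "replicate": rep,
                        "rand_index": rand_index(truth, labels),
                    }
                )
    return pd.DataFrame.from_records(records)
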