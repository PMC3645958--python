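"""Seeded synthetic-data generators.

Two families of test beds:

* **Module-structured gene expression** — five gene modules (clusters), each
  organized around a latent *eigengene*; a continuous outcome driven by two of
  the modules; 45% of genes are unstructured background noise.  Module gene
  ``g`` is ``r_g * eigengene + sqrt(1 - r_g^2) * noise`` with per-gene
  correlation ``r_g`` drawn uniformly from ``within_module_cor_range``, so
  module genes correlate with their eigengene (and causal-module genes with
  the outcome) while background genes carry no signal.  The continuous outcome
  can be median-dichotomized into a balanced binary one.
* **Gaussian two-class benchmarks** — the classical ringnorm, twonorm and
  threenorm problems (equal class priors, d-dimensional Gaussians).  Ringnorm
  separates the classes mainly by scale (covariance 4I vs I), so linear
  decision rules fail while quadratic terms recover the signal; twonorm is a
  mean-shift problem that linear rules solve; threenorm mixes the two.

All generators are pure functions of their design parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimDesign",
    "simulate_expression",
    "dichotomize_median",
    "make_benchmark",
    "BENCHMARK_NAMES",
]

BENCHMARK_NAMES = ("ringnorm", "twonorm", "threenorm")


@dataclass
class SimDesign:
    """Design of one module-structured expression simulation.

    Defaults: 5 equal-size modules, 2 of them driving the outcome, 45%
    background genes, per-gene module correlations in (0.3, 0.9), outcome
    noise standard deviation 0.5.
    """

    n_samples: int = 200
    n_genes: int = 500
    n_modules: int = 5
    n_causal_modules: int = 2
    background_fraction: float = 0.45
    within_module_cor_range: "tuple[float, float]" = (0.3, 0.9)
    outcome_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 20:
            raise ValueError("n_genes must be >= 20")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must lie in [0, 1)")
        lo, hi = self.within_module_cor_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("within_module_cor_range must lie inside (0, 1)")
        if self.n_causal_modules > self.n_modules:
            raise ValueError("n_causal_modules cannot exceed n_modules")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be nonnegative")


def simulate_expression(design: SimDesign):
    """Simulate ``(X, y_cont, module_labels)``.

    ``X`` is samples x genes; ``y_cont`` the continuous outcome (equal-weight
    sum of the causal-module eigengenes plus Gaussian noise);
    ``module_labels[g]`` is the 1-based module of gene ``g`` (0 = background).
    Modules 1 and 2 are the causal ones.
    """
    rng = np.random.default_rng(design.seed)
    n, G = design.n_samples, design.n_genes
    n_background = int(round(design.background_fraction * G))
    n_module_genes = G - n_background
    base, extra = divmod(n_module_genes, design.n_modules)
    sizes = [base + (1 if m < extra else 0) for m in range(design.n_modules)]

    eigengenes = rng.standard_normal((n, design.n_modules))
    X = np.empty((n, G))
    labels = np.zeros(G, dtype=int)
    lo, hi = design.within_module_cor_range
    g0 = 0
    for m, size in enumerate(sizes):
        r = rng.uniform(lo, hi, size=size)
        noise = rng.standard_normal((n, size))
        X[:, g0 : g0 + size] = (
            r * eigengenes[:, [m]] + np.sqrt(1.0 - r**2) * noise
        )
        labels[g0 : g0 + size] = m + 1
        g0 += size
    X[:, g0:] = rng.standard_normal((n, G - g0))

    y = eigengenes[:, : design.n_causal_modules].sum(axis=1)
    y = y + rng.normal(0.0, design.outcome_noise_sd, size=n)
    return X, y, labels


def dichotomize_median(y_cont: np.ndarray) -> np.ndarray:
    """Binary outcome: 1 where the value exceeds the median, else 0.

    With an even number of all-distinct values the classes are exactly
    balanced; values tied with the median go to class 0 (strict >).
    """
    y = np.asarray(y_cont, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant; cannot dichotomize")
    return (y > np.median(y)).astype(int)


def make_benchmark(
    name: str, n: int, d: int = 20, rng: "np.random.Generator | int | None" = None
):
    """Generate one of the Gaussian two-class benchmark problems.

    ringnorm  : class 0 ~ N(0, 4I); class 1 ~ N(a*1, I), a = 1/sqrt(d)
    twonorm   : class 0 ~ N(a*1, I); class 1 ~ N(-a*1, I), a = 2/sqrt(d)
    threenorm : class 0 ~ equal mixture of N(a*1, I) and N(-a*1, I);
                class 1 ~ N((a,-a,a,-a,...), I), a = 2/sqrt(d)

    Class labels are drawn with equal priors.  Returns ``(X, y)``.
    """
    if name not in BENCHMARK_NAMES:
        raise ValueError(f"unknown benchmark {name!r}; choose from {BENCHMARK_NAMES}")
    if n < 2:
        raise ValueError("n must be >= 2")
    if d < 1:
        raise ValueError("d must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = rng.integers(0, 2, size=n)
    X = rng.standard_normal((n, d))
    if name == "ringnorm":
        a = 1.0 / np.sqrt(d)
        X[y == 0] *= 2.0
        X[y == 1] += a
    elif name == "twonorm":
        a = 2.0 / np.sqrt(d)
        X[y == 0] += a
        X[y == 1] -= a
    else:  # threenorm
        a = 2.0 / np.sqrt(d)
        side = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        mask0 = y == 0
        X[mask0] += side[mask0, None] * a
        alt = a * np.where(np.arange(d) % 2 == 0, 1.0, -1.0)
        X[y == 1] += alt
    return X, y
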