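"""Ground-truth response surfaces and simulated treatment datasets.

The generator emulates the statistical structure of the treatment-mean
dataset: a smooth nonnegative dose–response surface over the 5-D culture
input box (four light channels in [0, 100] μmol/m²/s, sucrose in [1, 6] %
w/v), sampled on a factorial design with a small number of replicate
plantlets per treatment whose noise standard deviation scales with the
surface value (constant coefficient of variation, matching the observed
growth of SEs with means). Surfaces are additive Gaussian bumps per input,
optionally with pairwise interactions, so the argmax and the input
importance ordering are known analytically and every downstream stage
(model fitting, sensitivity ranking, optimization) can be tested against a
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from cultivopt.dataset import (
    INPUT_BOUNDS,
    INPUT_NAMES,
    GrowthDataset,
    Treatment,
    TreatmentRecord,
    load_table1,
)


class SyntheticError(ValueError):
    pass


DEFAULT_BOUNDS = np.array(INPUT_BOUNDS)


@dataclass(frozen=True)
class SurfaceConfig:
    """Parameters of an additive-Gaussian-bump response surface.

    ``amplitudes`` double as importance weights: the larger an input's bump
    amplitude, the more the response varies along that input. ``centers``
    are bump locations inside the bounds (the surface argmax when there are
    no interactions), ``widths`` are bump length scales in input units.
    ``noise_cv`` is the replicate coefficient of variation; the fixture's
    trait SEs correspond to per-plantlet CVs of roughly 0.2–0.6, so 0.3 is
    used as the realistic default.
    """

    baseline: float = 20.0
    amplitudes: tuple[float, ...] | None = None
    centers: tuple[float, ...] | None = None
    widths: tuple[float, ...] | None = None
    interactions: tuple[tuple[int, int, float], ...] = ()
    noise_cv: float = 0.3
    bounds: tuple[tuple[float, float], ...] = INPUT_BOUNDS


@dataclass(frozen=True)
class SurfaceSpec:
    """A concrete surface with analytically known argmax and importance order."""

    baseline: float
    amplitudes: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    interactions: tuple[tuple[int, int, float], ...]
    noise_cv: float
    bounds: np.ndarray

    @property
    def known_argmax(self) -> np.ndarray:
        """Bump centers; exact argmax for purely additive surfaces."""
        return self.centers.copy()

    @property
    def importance_order(self) -> np.ndarray:
        """Input indices sorted by decreasing amplitude (ties by index)."""
        return np.argsort(-self.amplitudes, kind="stable")

    def __call__(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (X - self.centers) / self.widths
        val = self.baseline + np.sum(
            self.amplitudes * np.exp(-(z**2)), axis=1
        )
        for i, j, a in self.interactions:
            val = val + a * np.exp(-(z[:, i] ** 2) - z[:, j] ** 2)
        return val


def make_surface(seed: int, config: SurfaceConfig = SurfaceConfig()) -> SurfaceSpec:
    """Build a surface; unspecified centers/widths/amplitudes are drawn
    reproducibly from ``seed``.

    Random centers fall in the central 60 % of each dimension so the argmax
    is identifiable from a box-filling design; random amplitudes are drawn
    strictly ordered so the planted importance ranking is unambiguous.
    """
    bounds = np.asarray(config.bounds, dtype=float)
    if bounds.ndim != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise SyntheticError("invalid bounds")
    d = bounds.shape[0]
    rng = np.random.default_rng(seed)
    span = bounds[:, 1] - bounds[:, 0]
    if config.centers is None:
        centers = bounds[:, 0] + span * (0.2 + 0.6 * rng.random(d))
    else:
        centers = np.asarray(config.centers, dtype=float)
        if np.any(centers < bounds[:, 0]) or np.any(centers > bounds[:, 1]):
            raise SyntheticError("centers outside bounds")
    if config.widths is None:
        widths = span * (0.25 + 0.25 * rng.random(d))
    else:
        widths = np.asarray(config.widths, dtype=float)
        if np.any(widths <= 0):
            raise SyntheticError("widths must be positive")
    if config.amplitudes is None:
        # strictly ordered magnitudes, shuffled over inputs
        mags = np.sort(10.0 + 90.0 * rng.random(d))[::-1]
        order = rng.permutation(d)
        amplitudes = np.empty(d)
        amplitudes[order] = mags
    else:
        amplitudes = np.asarray(config.amplitudes, dtype=float)
    if config.baseline < 0 or config.baseline + min(
        0.0, float(np.sum(np.minimum(amplitudes, 0.0)))
    ) < 0:
        raise SyntheticError("surface must be nonnegative over the box")
    if config.noise_cv < 0:
        raise SyntheticError("noise_cv must be nonnegative")
    return SurfaceSpec(
        baseline=float(config.baseline),
        amplitudes=amplitudes,
        centers=centers,
        widths=widths,
        interactions=tuple(config.interactions),
        noise_cv=float(config.noise_cv),
        bounds=bounds,
    )


def default_design() -> tuple[Treatment, ...]:
    """The fixture's factorial design: 22 LED spectra × sucrose {1, 3, 6}."""
    return tuple(r.treatment for r in load_table1().records)


#: Amplitudes of the parameter-recovery study surface: the rank-1 input is
#: clearly dominant (×1.67 over rank 2) so importance recovery is
#: identifiable, while every input keeps substantial curvature so the
#: argmax is identifiable in all five dimensions.
RECOVERY_AMPLITUDES = (150.0, 90.0, 75.0, 62.0, 50.0)


def make_recovery_study(
    seed: int,
    n_design: int = 600,
    n_rep: int = 4,
    noise_cv: float = 0.05,
) -> tuple[SurfaceSpec, GrowthDataset]:
    """A seeded parameter-recovery study: planted surface + simulated data.

    The surface uses the strictly ordered :data:`RECOVERY_AMPLITUDES`
    (assignment to inputs permuted by seed), equal widths of 0.45 of each
    dimension's span, and bump centers drawn in the central 20 % of the
    box — kernel surrogates estimate interior optima without the boundary
    bias that affects optima near a box face. The design is uniform
    space-filling: a 5-D response surface cannot be localized to a tenth
    of the box per dimension from a handful of factor levels.
    """
    bounds = DEFAULT_BOUNDS
    span = bounds[:, 1] - bounds[:, 0]
    rng = np.random.default_rng(seed)
    amplitudes = np.empty(5)
    amplitudes[rng.permutation(5)] = RECOVERY_AMPLITUDES
    centers = bounds[:, 0] + span * (0.4 + 0.2 * rng.random(5))
    surface = make_surface(
        seed,
        SurfaceConfig(
            amplitudes=tuple(amplitudes),
            centers=tuple(centers),
            widths=tuple(0.45 * span),
            noise_cv=noise_cv,
        ),
    )
    X = bounds[:, 0] + span * rng.random((n_design, 5))
    design = [Treatment(*row) for row in X]
    dataset = simulate_dataset(surface, design, n_rep=n_rep, seed=seed)
    return surface, dataset


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Draws from N(mean, sd) truncated below at 0."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def simulate_dataset(
    surface: SurfaceSpec | dict[str, SurfaceSpec],
    design: Sequence[Treatment],
    n_rep: int = 4,
    seed: int = 0,
    trait: str = "shoot_length",
) -> GrowthDataset:
    """Simulate a treatment-mean dataset from one or more surfaces.

    Per treatment and trait, ``n_rep`` replicate plantlet values are drawn
    from a zero-truncated normal with mean equal to the surface value and
    standard deviation ``noise_cv × value``; the record stores their sample
    mean and SE. The truncation keeps growth quantities nonnegative at the
    cost of a small positive bias when ``noise_cv`` is large relative to
    the mean.
    """
    if n_rep < 1:
        raise SyntheticError("n_rep must be >= 1")
    if not design:
        raise SyntheticError("empty design")
    surfaces = surface if isinstance(surface, dict) else {trait: surface}
    rng = np.random.default_rng(seed)
    records = []
    for tr in design:
        x = tr.as_array()[None, :]
        means, ses = {}, {}
        for name, surf in surfaces.items():
            val = float(surf(x)[0])
            draws = _truncated_normal(rng, val, surf.noise_cv * val, n_rep)
            means[name] = float(draws.mean())
            ses[name] = (
                float(draws.std(ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0
            )
        records.append(
            TreatmentRecord(
                treatment=tr,
                trait_means=means,
                trait_ses=ses,
                n_replicates=n_rep,
            )
        )
    return GrowthDataset(tuple(records))


def pseudo_replicates(dataset: GrowthDataset, seed: int = 0, n_draws: int | None = None):
    """Reconstruct plausible per-plantlet rows from treatment means and SEs.

    Per record, draws ``n_replicates`` (or ``n_draws``) values from a
    zero-truncated normal with mean = record mean and sd = SE·√n, the
    plantlet-level standard deviation implied by the reported standard
    error.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for r in dataset.records:
        n = n_draws or r.n_replicates
        draws = {
            t: _truncated_normal(
                rng, r.trait_means[t], r.trait_ses[t] * np.sqrt(r.n_replicates), n
            )
            for t in r.traits
        }
        for i in range(n):
            row = dict(zip(INPUT_NAMES, r.treatment.as_array()))
            row["plantlet"] = i + 1
            for t in r.traits:
                row[t] = float(draws[t][i])
            rows.append(row)
    return pd.DataFrame(rows)
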