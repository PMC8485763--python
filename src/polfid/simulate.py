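"""Synthetic-data generators with known ground truth.

Three kinds of raw input are emulated, matching what the analysis pipelines
consume:

* fluctuation-assay mutant counts (Poisson number of mutations per culture,
  Lea–Coulson clone sizes, binomial partial plating);
* alkaline-gel lanes of nicked single-stranded genomic DNA (uniform nicks on a
  linear molecule, mass-proportional staining, log-size electrophoretic
  migration, Gaussian band spread and noise);
* per-isolate base-substitution calls in the rpoB reporter window (multinomial
  over the six base-pair substitution classes and a per-position weight map).

All generators take an explicit integer seed (or a ``numpy.random.Generator``)
and never touch global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError
from .gelquant import LaneProfile
from .spectra import (
    COMPLEMENT,
    SUBSTITUTION_CLASSES,
    WINDOW_HI,
    WINDOW_LO,
    SubstitutionCall,
)

__all__ = [
    "SimConfig",
    "simulate_fluctuation_counts",
    "simulate_nicked_fragments",
    "simulate_lane_fragments",
    "render_gel_lane",
    "simulate_substitution_calls",
]

# six-class substitution probabilities of a typical wild-type replicase
# spectrum in a proofreading-deficient background (AT->CG dominated), in the
# order of SUBSTITUTION_CLASSES
_DEFAULT_CLASS_PROBS = (2 / 302, 8 / 302, 9 / 302, 89 / 302, 174 / 302, 20 / 302)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Ground-truth parameters shared by the three generators.

    Defaults describe the study conditions the pipelines are validated
    against: 30 parallel cultures with m = 2 expected mutations each and full
    plating; a 9.28e6-nt single-strand genome nicked at rho = 5e-5 per
    nucleotide (about 465 breakpoints per strand, the scale observed for an
    RER-deficient wild-type replicase); and a wild-type-like substitution
    spectrum over the rpoB window.
    """

    seed: int = 0
    # fluctuation assay
    n_cultures: int = 30
    m_true: float = 2.0
    epsilon: float = 1.0
    Nt: int = 200_000_000
    # nicked-genome gel
    G: int = 9_280_000
    rho: float = 5e-5
    n_molecules: int = 20
    calib_a: float = 450.0
    calib_b: float = -25.0
    band_sigma: float = 1.5
    noise_sd: float = 20.0
    background: float = 2000.0
    n_grid: int = 800
    grid_lo: float | None = None
    grid_hi: float | None = None
    # substitution spectrum
    class_probs: tuple[float, ...] = _DEFAULT_CLASS_PROBS
    position_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ParameterError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.m_true < 0:
            raise ParameterError("m_true must be >= 0")
        if self.Nt < 1:
            raise ParameterError("Nt must be >= 1")
        if self.G < 1:
            raise ParameterError("G must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError(f"rho must be in [0, 1), got {self.rho}")
        if self.calib_b >= 0:
            raise ParameterError("calib_b must be negative (larger fragments migrate less)")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.size != len(SUBSTITUTION_CLASSES) or np.any(probs < 0):
            raise ParameterError("class_probs must be 6 non-negative values")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ParameterError("class_probs must sum to 1 within 1e-9")

    def distance_of_size(self, sz: np.ndarray | float) -> np.ndarray | float:
        """Migration distance of a fragment of ``sz`` nucleotides."""
        return self.calib_a + self.calib_b * np.log(sz)

    def default_grid(self) -> np.ndarray:
        """Distance grid spanning fragment sizes from the full genome to ~150 nt."""
        lo = self.grid_lo
        hi = self.grid_hi
        if lo is None:
            lo = float(self.distance_of_size(float(self.G))) - 5.0 * self.band_sigma
        if hi is None:
            hi = float(self.distance_of_size(150.0)) + 5.0 * self.band_sigma
        return np.linspace(lo, hi, self.n_grid)


def simulate_fluctuation_counts(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw resistant-colony counts for ``cfg.n_cultures`` parallel cultures.

    Per culture: M ~ Poisson(m_true) mutations; each founds a clone of size
    Y = min(floor(1/U), Nt); Binomial(Y, epsilon) of its cells are plated.
    """
    rng = _as_rng(cfg.seed) if rng is None else rng
    n_mut = rng.poisson(cfg.m_true, size=cfg.n_cultures)
    total = int(n_mut.sum())
    counts = np.zeros(cfg.n_cultures, dtype=np.int64)
    if total == 0 or cfg.epsilon == 0.0:
        return counts
    u = rng.random(total)
    clone = np.minimum(np.floor(1.0 / u), float(cfg.Nt)).astype(np.int64)
    if cfg.epsilon == 1.0:
        obs = clone
    else:
        obs = rng.binomial(clone, cfg.epsilon)
    culture_idx = np.repeat(np.arange(cfg.n_cultures), n_mut)
    np.add.at(counts, culture_idx, obs)
    return counts


def simulate_nicked_fragments(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Fragment sizes of one linear single-strand molecule nicked at rate rho.

    K ~ Binomial(G-1, rho) distinct internal nick positions are placed
    uniformly; the K+1 inter-nick segment lengths are returned and always sum
    to G exactly.
    """
    rng = _as_rng(cfg.seed) if rng is None else rng
    G = cfg.G
    k = int(rng.binomial(G - 1, cfg.rho)) if cfg.rho > 0 else 0
    if k == 0:
        return np.array([G], dtype=np.int64)
    # distinct cut points in [1, G-1]; redraw the rare collisions
    cuts = np.unique(rng.integers(1, G, size=k))
    while cuts.size < k:
        extra = rng.integers(1, G, size=k - cuts.size)
        cuts = np.unique(np.concatenate([cuts, extra]))
    edges = np.concatenate([[0], cuts, [G]])
    return np.diff(edges).astype(np.int64)


def simulate_lane_fragments(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Pooled fragments of ``cfg.n_molecules`` genome equivalents in one lane."""
    rng = _as_rng(cfg.seed) if rng is None else rng
    return np.concatenate(
        [simulate_nicked_fragments(cfg, rng) for _ in range(cfg.n_molecules)]
    )


def render_gel_lane(
    fragments: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    label: str = "",
    genotype_flags: dict | None = None,
    uniform_mass: bool = False,
) -> LaneProfile:
    """Render a densitometry profile for a list of fragment sizes.

    Each fragment of size ``sz`` migrates to d = calib_a + calib_b*ln(sz) and
    deposits total intensity proportional to its mass (``sz``; or 1 per
    fragment with ``uniform_mass=True``, appropriate for equimolar ladder
    bands), spread as a Gaussian of width ``band_sigma`` on the distance grid,
    on top of a constant background with additive Gaussian noise.
    """
    rng = _as_rng(cfg.seed) if rng is None else rng
    fragments = np.asarray(fragments, dtype=float)
    if np.any(fragments <= 0):
        raise DataError("fragment sizes must be positive")
    grid = cfg.default_grid()
    dx = grid[1] - grid[0]
    intensity = np.zeros_like(grid)
    if fragments.size:
        centers = np.asarray(cfg.distance_of_size(fragments), dtype=float)
        # equimolar ladder bands are loaded to be equally visible: give each
        # band the mean mass instead of its own size
        mass = np.full_like(fragments, fragments.mean()) if uniform_mass else fragments
        # bin width times the normal density: each fragment's mass integrates
        # to ~`mass` over the grid
        z = (grid[None, :] - centers[:, None]) / cfg.band_sigma
        kernel = np.exp(-0.5 * z**2) * (dx / (cfg.band_sigma * math.sqrt(2.0 * math.pi)))
        intensity = mass @ kernel
    intensity = intensity + cfg.background
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return LaneProfile(
        distances=grid,
        intensities=np.maximum(intensity, 0.0),
        label=label,
        genotype_flags=genotype_flags or {},
    )


def simulate_substitution_calls(
    cfg: SimConfig,
    n_isolates: int,
    rng: np.random.Generator | None = None,
) -> list[SubstitutionCall]:
    """One substitution call per isolate, with class and position ground truth.

    The class is drawn from ``cfg.class_probs``; the position from
    ``cfg.position_weights`` (uniform over the rpoB reporter window when not
    given); the recorded (ref, alt) pair is one of the two strand
    representations of the class, chosen with equal probability.
    """
    rng = _as_rng(cfg.seed) if rng is None else rng
    if n_isolates < 0:
        raise ParameterError("n_isolates must be >= 0")
    if cfg.position_weights is None:
        positions = np.arange(WINDOW_LO, WINDOW_HI + 1)
        weights = np.ones(positions.size)
    else:
        positions = np.array(sorted(cfg.position_weights), dtype=int)
        weights = np.array([cfg.position_weights[p] for p in positions], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ParameterError("position_weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    calls: list[SubstitutionCall] = []
    cls_idx = rng.choice(len(SUBSTITUTION_CLASSES), size=n_isolates, p=np.asarray(cfg.class_probs))
    pos_idx = rng.choice(positions.size, size=n_isolates, p=weights)
    flip = rng.random(n_isolates) < 0.5
    for i in range(n_isolates):
        cls = SUBSTITUTION_CLASSES[cls_idx[i]]
        pair_from, pair_to = cls.split("->")
        ref, alt = pair_from[0], pair_to[0]
        if flip[i]:
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        calls.append(
            SubstitutionCall(
                position=int(positions[pos_idx[i]]),
                ref=ref,
                alt=alt,
                isolate=f"iso{i:05d}",
            )
        )
    return calls
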