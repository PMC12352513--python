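"""Ground-truth generators for every input the pipeline consumes.

Factorial scene batches shaded with the Ward model at two roughness levels,
hemi-icosphere viewpoint sampling, planted-highlight toy images for metric
oracles, and simulated observers for both behavioural tasks:

* quadruplet choices ("which pair shows the larger gloss difference") follow
  a Thurstone Case V model on latent pair visibilities, and
* 2AFC gloss judgments follow a cumulative-normal psychometric function on
  log roughness with a symmetric lapse rate.

Every routine takes an explicit seed and is bitwise reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .render import Light, SceneSpec, WardMaterial

__all__ = [
    "FactorialDesign",
    "LatentVisibility",
    "PsychometricParams",
    "PAPER_MATERIAL_RHO_S",
    "PAPER_MATERIAL_RHO_D",
    "ALPHA_PAIR",
    "STANDARD_ALPHA",
    "ROUGHNESS_LADDER",
    "default_lights",
    "default_shapes",
    "make_factorial_scenes",
    "sample_viewpoints_hemiicosphere",
    "icosphere_vertices",
    "simulate_quadruplet_observer",
    "simulate_2afc_observer",
    "make_toy_images",
    "TRIAL_COLUMNS",
]

# Study material: fixed reflectance, greenish diffuse triplet, and the
# high/low-gloss roughness pair used throughout.
PAPER_MATERIAL_RHO_S = 0.066
PAPER_MATERIAL_RHO_D = (0.1, 0.3, 0.1)
ALPHA_PAIR = (0.01, 0.19)

# Method-of-constant-stimuli ladder: standard roughness 0.1 and ten
# log-spaced comparison levels around it.
STANDARD_ALPHA = 0.1
ROUGHNESS_LADDER = (
    0.0702, 0.0824, 0.0901, 0.0950, 0.0981,
    0.1019, 0.1050, 0.1099, 0.1176, 0.1298,
)

TRIAL_COLUMNS = ["participant_id", "trial_index", "item_a", "item_b",
                 "choice", "phase", "rep"]


@dataclass(frozen=True)
class FactorialDesign:
    """Fully crossed shapes × lights × viewpoints design."""

    shapes: tuple = ()
    lights: tuple = ()
    viewpoints: tuple = ()
    roughness_pair: tuple[float, float] = ALPHA_PAIR
    seed: int = 0

    @property
    def n_scenes(self) -> int:
        return len(self.shapes) * len(self.lights) * len(self.viewpoints)


@dataclass(frozen=True)
class LatentVisibility:
    """Thurstonian latents: one discriminability d per scene, common noise."""

    d: tuple[float, ...]
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("latent d must be finite")


@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-normal psychometric function on log roughness."""

    pse: float  # log-roughness point of subjective equality
    slope: float  # 1 / log-units
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def p_choose_comparison(self, log_alpha_cmp) -> np.ndarray:
        """P(judge the comparison glossier); decreasing in roughness."""
        z = self.slope * (self.pse - np.asarray(log_alpha_cmp, dtype=float))
        return self.lapse + (1.0 - 2.0 * self.lapse) * norm.cdf(z)


# ---------------------------------------------------------------------------
# Scene factories
# ---------------------------------------------------------------------------

def default_shapes(n: int = 3) -> tuple:
    """Parametric shape roster spanning smooth to bumpy surfaces."""
    roster = (
        ("sphere", {}),
        ("superellipsoid", {"exponent": 4.0}),
        ("bumpy_sphere", {"bump_amplitude": 0.08, "bump_frequency": 6.0}),
        ("superellipsoid", {"exponent": 2.5}),
        ("bumpy_sphere", {"bump_amplitude": 0.05, "bump_frequency": 9.0}),
    )
    return tuple(itertools.islice(itertools.cycle(roster), n))


def default_lights(n: int = 3) -> tuple:
    """Lighting roster from a hard point light to pure ambient."""
    roster = (
        (Light("point", (40.0, 40.0, 40.0), position=(2.0, -1.0, 3.0)),),
        (Light("directional", (3.0, 3.0, 3.0), direction=(0.3, -0.4, 0.87)),
         Light("ambient", (0.15, 0.15, 0.15))),
        (Light("ambient", (0.8, 0.8, 0.8)),),
        (Light("point", (25.0, 25.0, 25.0), position=(-2.0, 2.0, 2.5)),
         Light("ambient", (0.1, 0.1, 0.1))),
        (Light("directional", (4.0, 4.0, 4.0), direction=(-0.5, 0.0, 0.866)),),
    )
    return tuple(itertools.islice(itertools.cycle(roster), n))


def make_factorial_scenes(design: FactorialDesign,
                          image_size: int = 96) -> list[tuple[SceneSpec, SceneSpec]]:
    """One (low-roughness, high-roughness) scene pair per design cell.

    Within a pair the two specs are identical in every field except the
    material's alpha.
    """
    if not (design.shapes and design.lights and design.viewpoints):
        raise ValueError("all three factor lists must be non-empty")
    a_low, a_high = design.roughness_pair
    pairs = []
    for (shape_id, shape_params), lights, (elev, azim) in itertools.product(
            design.shapes, design.lights, design.viewpoints):
        base = SceneSpec(
            shape_id=shape_id,
            lights=tuple(lights),
            viewpoint=(float(elev), float(azim), 3.0),
            material=WardMaterial(PAPER_MATERIAL_RHO_S, PAPER_MATERIAL_RHO_D, a_low),
            image_size=image_size,
            shape_params=dict(shape_params),
        )
        pairs.append((base, base.with_alpha(a_high)))
    return pairs


# ---------------------------------------------------------------------------
# Hemi-icosphere viewpoints
# ---------------------------------------------------------------------------

def icosphere_vertices(subdivisions: int = 1) -> np.ndarray:
    """Unit icosphere vertices after the given number of subdivisions."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(map(tuple, verts))
    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = np.array(verts[a]) + np.array(verts[b])
                m /= np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(tuple(m))
            return cache[key]

        for (a, b, c) in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.array(verts)


def sample_viewpoints_hemiicosphere(n: int, subdivisions: int = 1) -> list[tuple[float, float]]:
    """n well-separated (elevation, azimuth) directions above the horizon.

    Candidates are the upper-hemisphere vertices of a subdivided icosphere;
    selection is deterministic farthest-point greedy seeded at the vertex
    nearest the zenith, so repeated calls agree exactly.
    """
    verts = icosphere_vertices(subdivisions)
    upper = verts[verts[:, 2] >= -1e-9]
    # canonical order so greedy is permutation-independent
    upper = upper[np.lexsort((upper[:, 1], upper[:, 0], -upper[:, 2]))]
    if n > len(upper):
        raise ValueError(f"requested {n} viewpoints; only {len(upper)} vertices available")
    chosen = [int(np.argmax(upper[:, 2]))]
    while len(chosen) < n:
        dots = upper @ upper[chosen].T  # cosine similarity to chosen set
        closest = dots.max(axis=1)
        closest[chosen] = np.inf
        chosen.append(int(np.argmin(closest)))
    out = []
    for i in chosen:
        x, y, z = upper[i]
        out.append((float(np.rad2deg(np.arcsin(np.clip(z, -1, 1)))),
                    float(np.rad2deg(np.arctan2(y, x)) % 360.0)))
    return out


# ---------------------------------------------------------------------------
# Simulated observers
# ---------------------------------------------------------------------------

def simulate_quadruplet_observer(
    latents: LatentVisibility,
    n_reps: int = 6,
    participant_id: str = "sim0",
    seed: int = 0,
    practice_accuracy: float = 1.0,
    n_practice: int = 20,
) -> pd.DataFrame:
    """Trial table for one observer on the pairs-of-pairs ranking task.

    Every unordered scene pair (i, j) is shown ``n_reps`` times;
    P(choose i) = Phi((d_i - d_j) / (sigma * sqrt(2))) (Thurstone Case V).
    Practice trials with known answers are prepended; the observer answers
    them correctly with probability ``practice_accuracy``.
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(latents.d, dtype=float)
    n_scenes = d.size
    rows = []
    t = 0
    for p in range(n_practice):
        correct = rng.random() < practice_accuracy
        rows.append((participant_id, t, -1, -2, -1 if correct else -2, "practice", 0))
        t += 1
    pairs = list(itertools.combinations(range(n_scenes), 2))
    for rep in range(n_reps):
        order = rng.permutation(len(pairs))
        for idx in order:
            i, j = pairs[idx]
            p_i = norm.cdf((d[i] - d[j]) / (latents.sigma * np.sqrt(2.0)))
            choice = i if rng.random() < p_i else j
            rows.append((participant_id, t, i, j, choice, "main", rep))
            t += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_2afc_observer(
    params: PsychometricParams,
    standard_alpha: float = STANDARD_ALPHA,
    comparison_alphas=ROUGHNESS_LADDER,
    n_reps: int = 40,
    participant_id: str = "sim0",
    scene_id: str = "scene0",
    seed: int = 0,
) -> pd.DataFrame:
    """Method-of-constant-stimuli 2AFC trials from a known psychometric curve.

    Each comparison level is shown ``n_reps`` times in random order; the
    response is a Bernoulli draw of "comparison glossier" at the curve value.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.repeat(np.asarray(comparison_alphas, dtype=float), n_reps)
    reps = np.tile(np.arange(n_reps), len(comparison_alphas))
    order = rng.permutation(len(levels))
    levels, reps = levels[order], reps[order]
    p = params.p_choose_comparison(np.log(levels))
    responses = rng.random(len(levels)) < p
    return pd.DataFrame({
        "scene_id": scene_id,
        "participant_id": participant_id,
        "trial_index": np.arange(len(levels)),
        "standard_alpha": standard_alpha,
        "comparison_alpha": levels,
        "response": responses,
        "rep": reps,
    })


# ---------------------------------------------------------------------------
# Toy images with known metric values
# ---------------------------------------------------------------------------

def make_toy_images(kind: str, size: int = 64, seed: int = 0, **params):
    """Deterministic (luminance image, mask) fixtures with known statistics.

    Kinds: ``uniform`` (level), ``planted_highlight`` (disk mask of radius
    ``mask_radius`` with a bright disk of ``highlight_radius``), ``sinusoid``
    (horizontal grating, ``frequency`` cycles/image), ``step_edge`` (vertical
    step of ``amplitude``), ``ramp`` (linear ramp of the same range),
    ``noise`` (seeded smooth Gaussian texture).
    """
    if size <= 0:
        raise ValueError("size must be positive")
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.ones((size, size), dtype=bool)
    if kind == "uniform":
        img = np.full((size, size), float(params.get("level", 10.0)))
    elif kind == "planted_highlight":
        cx = cy = (size - 1) / 2.0
        r_mask = params.get("mask_radius", size * 0.45)
        r_high = params.get("highlight_radius", size * 0.12)
        dist = np.hypot(yy - cy, xx - cx)
        mask = dist <= r_mask
        img = np.where(dist <= r_high, float(params.get("peak", 90.0)),
                       float(params.get("base", 2.0)))
        img = np.where(mask, img, 0.0)
    elif kind == "sinusoid":
        f = float(params.get("frequency", 4.0))
        amp = float(params.get("amplitude", 1.0))
        img = params.get("offset", 10.0) + amp * np.sin(2 * np.pi * f * xx / size)
    elif kind == "step_edge":
        amp = float(params.get("amplitude", 10.0))
        img = np.where(xx >= size // 2, amp, 0.0).astype(float)
    elif kind == "ramp":
        amp = float(params.get("amplitude", 10.0))
        img = amp * xx / (size - 1)
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        img = rng.normal(10.0, 2.0, (size, size))
        img = np.clip(img, 0, None)
    else:
        raise ValueError(f"unknown toy image kind {kind!r}")
    return img.astype(np.float64), mask
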