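"""Analytic forward renderer for matched pairs of glossy objects.

The renderer shades parametric shapes (sphere, superellipsoid, bumpy sphere)
with the energy-conserving Ward reflectance model under point, directional and
ambient lights, using an orthographic camera.  It produces linear HDR radiance
images; :func:`tonemap_reinhard`, :func:`encode_srgb` and
:func:`display_luminance` carry those through the photographic tone-mapping
operator and a calibrated display model to luminance in cd/m².

Local shading only: no shadows, interreflections or Fresnel effects.  The
point of the renderer is to produce pixel-aligned image pairs that differ only
in surface roughness, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "WardMaterial",
    "Light",
    "SceneSpec",
    "HDRImage",
    "ToneMapParams",
    "DisplayModel",
    "ward_brdf",
    "render_scene",
    "tonemap_reinhard",
    "encode_srgb",
    "decode_srgb",
    "display_luminance",
    "luminance_709",
]

Component = Literal["full", "diffuse_only", "specular_only"]

#: Rec. 709 luma weights used to collapse linear RGB to luminance.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class WardMaterial:
    """Ward reflectance parameters of one surface.

    Parameters
    ----------
    rho_s : float
        Specular reflectance in [0, 1].
    rho_d : tuple of float
        Diffuse reflectance per RGB channel, each in [0, 1].
    alpha : float
        Surface roughness (> 0); lower alpha means a sharper specular lobe,
        i.e. a glossier surface.
    """

    rho_s: float
    rho_d: tuple[float, float, float]
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_s <= 1.0:
            raise ValueError(f"rho_s must be in [0, 1], got {self.rho_s}")
        if any(not 0.0 <= c <= 1.0 for c in self.rho_d):
            raise ValueError(f"rho_d channels must be in [0, 1], got {self.rho_d}")
        if self.rho_s + max(self.rho_d) > 1.0 + 1e-12:
            raise ValueError("rho_s + max(rho_d) must not exceed 1 (energy plausibility)")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class Light:
    """One light source: ``point``, ``directional`` or ``ambient``.

    ``direction`` points from the scene toward a directional light;
    ``position`` locates a point light in world units.  ``intensity`` is a
    per-channel radiant intensity (point), irradiance on a perpendicular
    surface (directional) or ambient irradiance term.
    """

    type: Literal["point", "directional", "ambient"]
    intensity: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    position: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.type == "directional" and self.direction is None:
            raise ValueError("directional light needs a direction")
        if self.type == "point" and self.position is None:
            raise ValueError("point light needs a position")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one renderable scene."""

    shape_id: str
    lights: tuple[Light, ...]
    viewpoint: tuple[float, float, float]  # (elevation deg, azimuth deg, distance)
    material: WardMaterial
    image_size: int = 96
    background: tuple[float, float, float] = (0.02, 0.02, 0.02)
    shape_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lights:
            raise ValueError("scene needs at least one light")
        if not 0.0 <= self.viewpoint[0] <= 90.0:
            raise ValueError("elevation must be in [0, 90] degrees")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")

    def with_alpha(self, alpha: float) -> "SceneSpec":
        """Copy of this scene differing only in surface roughness."""
        mat = WardMaterial(self.material.rho_s, self.material.rho_d, alpha)
        return SceneSpec(
            self.shape_id, self.lights, self.viewpoint, mat,
            self.image_size, self.background, dict(self.shape_params),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        """Inverse of :meth:`to_dict` (JSON-friendly scene serialization)."""
        lights = tuple(
            Light(l["type"], tuple(l["intensity"]),
                  tuple(l["direction"]) if l.get("direction") else None,
                  tuple(l["position"]) if l.get("position") else None)
            for l in d["lights"])
        mat = d["material"]
        return cls(
            shape_id=d["shape_id"],
            lights=lights,
            viewpoint=tuple(d["viewpoint"]),
            material=WardMaterial(mat["rho_s"], tuple(mat["rho_d"]), mat["alpha"]),
            image_size=d.get("image_size", 96),
            background=tuple(d.get("background", (0.02, 0.02, 0.02))),
            shape_params=dict(d.get("shape_params", {})),
        )


@dataclass
class HDRImage:
    """Linear radiance raster (H, W, 3), relative units >= 0."""

    pixels: np.ndarray
    component: Component = "full"
    mask: np.ndarray | None = None  # object mask emitted by the renderer

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("HDRImage expects an (H, W, 3) array")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("radiance must be finite and non-negative")

    @property
    def luminance(self) -> np.ndarray:
        return luminance_709(self.pixels)


@dataclass(frozen=True)
class ToneMapParams:
    """Photographic tone-mapping parameters: key (middle-grey target) and burn."""

    key: float = 0.18
    burn: float = 0.0

    def __post_init__(self) -> None:
        if self.key <= 0:
            raise ValueError("key must be > 0")
        if self.burn < 0:
            raise ValueError("burn must be >= 0")


@dataclass(frozen=True)
class DisplayModel:
    """Calibrated display: peak/black luminance in cd/m² and angular resolution.

    ``gamma`` only records the display's configured decoding exponent; the
    calibration path itself uses the piecewise sRGB transfer function.
    """

    peak_luminance: float = 100.0
    black_level: float = 1.0
    ppd: float = 120.0
    gamma: float = 2.2

    def __post_init__(self) -> None:
        if not self.peak_luminance > self.black_level >= 0:
            raise ValueError("need peak_luminance > black_level >= 0")
        if self.ppd <= 0:
            raise ValueError("ppd must be > 0")


def luminance_709(rgb: np.ndarray) -> np.ndarray:
    """Linear-RGB to luminance with Rec. 709 weights."""
    return np.asarray(rgb, dtype=np.float64) @ _LUMA


# ---------------------------------------------------------------------------
# BRDF
# ---------------------------------------------------------------------------

def ward_brdf(
    incident: np.ndarray,
    outgoing: np.ndarray,
    normal: np.ndarray,
    mat: WardMaterial,
) -> np.ndarray:
    """Energy-conserving Ward BRDF (bounded-albedo variant), per channel.

    Diffuse term rho_d / pi plus the specular lobe

        f_s = rho_s / (pi a^2) * exp(-tan^2(th) / a^2)
              * 2 (1 + cos ti cos to) / (cos ti + cos to)^4

    where th is the half-angle between ``incident + outgoing`` and the normal.
    This variant keeps the directional-hemispherical albedo bounded by rho_s
    at all angles (the classic lobe can exceed 1 near grazing) and is
    Helmholtz-reciprocal by construction.

    All direction arguments may be broadcastable stacks of unit vectors with
    the vector axis last; the result has one extra trailing axis of size 3
    (RGB).  Invalid geometry (either cosine <= 0) yields exactly zero.
    """
    incident = np.asarray(incident, dtype=np.float64)
    outgoing = np.asarray(outgoing, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)

    cos_i = np.sum(incident * normal, axis=-1)
    cos_o = np.sum(outgoing * normal, axis=-1)
    valid = (cos_i > 0) & (cos_o > 0)

    rho_d = np.array(mat.rho_d)
    diffuse = rho_d / np.pi  # (3,)

    half = incident + outgoing
    half_norm = np.linalg.norm(half, axis=-1)
    # guard zero-length half vectors (i == -o cannot be valid anyway)
    hn = np.where(half_norm > 0, half_norm, 1.0)
    cos_h = np.sum(half * normal, axis=-1) / hn
    cos_h = np.clip(cos_h, 1e-12, 1.0)
    tan2_h = (1.0 - cos_h**2) / cos_h**2

    a2 = mat.alpha**2
    denom = np.clip(cos_i + cos_o, 1e-12, None) ** 4
    spec = (
        mat.rho_s / (np.pi * a2)
        * np.exp(-tan2_h / a2)
        * 2.0 * (1.0 + cos_i * cos_o)
        / denom
    )
    spec = np.where(valid, spec, 0.0)

    out = np.where(valid[..., None], diffuse, 0.0) + spec[..., None] * np.ones(3)
    return out


def _ward_components(incident, outgoing, normal, mat, component: Component):
    """BRDF restricted to one transport component."""
    if component == "diffuse_only":
        m = WardMaterial(0.0, mat.rho_d, mat.alpha)
    elif component == "specular_only":
        m = WardMaterial(mat.rho_s, (0.0, 0.0, 0.0), mat.alpha)
    else:
        m = mat
    return ward_brdf(incident, outgoing, normal, m)


# ---------------------------------------------------------------------------
# Geometry: orthographic ray casting against analytic shapes
# ---------------------------------------------------------------------------

def _camera_frame(elevation_deg: float, azimuth_deg: float):
    """Right-handed camera basis looking at the origin."""
    el = np.deg2rad(elevation_deg)
    az = np.deg2rad(azimuth_deg)
    view = np.array([
        np.cos(el) * np.cos(az),
        np.cos(el) * np.sin(az),
        np.sin(el),
    ])  # from object toward camera
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(up, view)
    if np.linalg.norm(right) < 1e-9:  # looking straight down
        right = np.array([1.0, 0.0, 0.0])
    right /= np.linalg.norm(right)
    cam_up = np.cross(view, right)
    return view, right, cam_up


def _implicit(shape_id: str, params: dict):
    """Return an implicit field F(p) (negative inside) for the shape."""
    if shape_id == "sphere":
        r = params.get("radius", 1.0)

        def F(p):
            return np.linalg.norm(p, axis=-1) - r

    elif shape_id == "superellipsoid":
        n = params.get("exponent", 4.0)
        r = params.get("radius", 1.0)

        def F(p):
            return (np.abs(p / r) ** n).sum(axis=-1) ** (1.0 / n) - 1.0

    elif shape_id == "bumpy_sphere":
        r = params.get("radius", 1.0)
        amp = params.get("bump_amplitude", 0.08)
        freq = params.get("bump_frequency", 6.0)

        def F(p):
            rad = np.linalg.norm(p, axis=-1)
            safe = np.clip(rad, 1e-9, None)
            theta = np.arccos(np.clip(p[..., 2] / safe, -1, 1))
            phi = np.arctan2(p[..., 1], p[..., 0])
            bump = amp * np.sin(freq * theta) * np.cos(freq * phi)
            return rad - (r + bump)

    else:
        raise ValueError(f"unknown shape_id: {shape_id!r}")
    return F


def _ray_march(F, origins: np.ndarray, direction: np.ndarray,
               t_max: float = 6.0, n_coarse: int = 192, n_bisect: int = 40):
    """Find first root of F along origin + t*direction for a bundle of rays.

    Coarse sampling locates the first sign change; bisection refines it.
    Returns (hit mask, hit points).
    """
    ts = np.linspace(0.0, t_max, n_coarse)
    # (n_rays, n_coarse, 3)
    pts = origins[:, None, :] + ts[None, :, None] * direction[None, None, :]
    vals = F(pts)
    inside = vals < 0
    first = inside.argmax(axis=1)  # first True, 0 if none
    hit = inside.any(axis=1) & (first > 0)

    idx = np.where(hit)[0]
    lo = ts[first[idx] - 1]
    hi = ts[first[idx]]
    o = origins[idx]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        v = F(o + mid[:, None] * direction[None, :])
        above = v > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    t_hit = 0.5 * (lo + hi)
    points = np.full_like(origins, np.nan)
    points[idx] = o + t_hit[:, None] * direction[None, :]
    return hit, points


def _numeric_normals(F, points: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Outward unit normals from central differences of the implicit field."""
    grads = np.empty_like(points)
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        grads[:, k] = (F(points + dp) - F(points - dp)) / (2 * h)
    norm = np.linalg.norm(grads, axis=-1, keepdims=True)
    return grads / np.clip(norm, 1e-12, None)


def render_scene(scene: SceneSpec, component: Component = "full") -> HDRImage:
    """Shade one scene; returns an :class:`HDRImage` with its object mask.

    Per-pixel outgoing radiance is the sum over point/directional lights of
    ``brdf * cos(theta_i) * incident irradiance`` plus ``ambient * rho_d``
    for ambient terms (ambient light excites only the diffuse component).
    Background pixels carry the constant background radiance (zero for the
    specular_only component, so that full = diffuse + specular everywhere).
    """
    if component not in ("full", "diffuse_only", "specular_only"):
        raise ValueError(f"unknown component {component!r}")
    n = scene.image_size
    view, right, cam_up = _camera_frame(scene.viewpoint[0], scene.viewpoint[1])
    half_extent = scene.shape_params.get("frame_half_extent", 1.3)

    # pixel centres at integer coordinates, origin top-left
    u = (np.arange(n) + 0.5) / n * 2 * half_extent - half_extent
    v = half_extent - (np.arange(n) + 0.5) / n * 2 * half_extent
    uu, vv = np.meshgrid(u, v)
    origins = (
        uu.ravel()[:, None] * right[None, :]
        + vv.ravel()[:, None] * cam_up[None, :]
        + scene.viewpoint[2] * view[None, :]
    )
    ray_dir = -view

    F = _implicit(scene.shape_id, scene.shape_params)
    hit, points = _ray_march(F, origins, ray_dir,
                             t_max=2.0 * scene.viewpoint[2])
    img = np.zeros((n * n, 3))
    if component != "specular_only":
        img[:] = np.array(scene.background)

    if hit.any():
        p = points[hit]
        normals = _numeric_normals(F, p)
        outgoing = np.broadcast_to(view, p.shape)
        radiance = np.zeros_like(p)
        rho_d = np.array(scene.material.rho_d)
        for light in scene.lights:
            inten = np.array(light.intensity)
            if light.type == "ambient":
                if component != "specular_only":
                    radiance += inten[None, :] * rho_d[None, :]
                continue
            if light.type == "directional":
                wi = np.array(light.direction, dtype=float)
                wi = wi / np.linalg.norm(wi)
                wi = np.broadcast_to(wi, p.shape)
                irradiance = inten[None, :]
            else:  # point
                to_light = np.array(light.position, dtype=float)[None, :] - p
                dist2 = np.sum(to_light**2, axis=-1, keepdims=True)
                wi = to_light / np.sqrt(dist2)
                irradiance = inten[None, :] / dist2
            f = _ward_components(wi, outgoing, normals, scene.material, component)
            cos_i = np.clip(np.sum(wi * normals, axis=-1), 0.0, None)
            radiance += f * cos_i[:, None] * irradiance
        img[hit] = radiance

    mask = hit.reshape(n, n)
    return HDRImage(img.reshape(n, n, 3), component=component, mask=mask)


# ---------------------------------------------------------------------------
# Tone mapping and display calibration
# ---------------------------------------------------------------------------

def tonemap_reinhard(img: HDRImage | np.ndarray,
                     params: ToneMapParams = ToneMapParams()) -> np.ndarray:
    """Photographic tone mapping, global operator.

    With burn = 0 the operator reduces to L_d = L' / (1 + L') where
    L' = key * L / geometric-mean(L); colour is preserved by scaling RGB by
    L_d / L.  Output is display-linear in [0, 1].
    """
    pixels = img.pixels if isinstance(img, HDRImage) else np.asarray(img, dtype=np.float64)
    L = luminance_709(pixels)
    if np.all(L <= 0):
        return np.zeros_like(pixels)
    log_mean = np.exp(np.mean(np.log(L + 1e-9)))
    Lp = params.key * L / log_mean
    if params.burn > 0:
        white = params.burn * Lp.max() if Lp.max() > 0 else 1.0
        Ld = Lp * (1.0 + Lp / white**2) / (1.0 + Lp)
    else:
        Ld = Lp / (1.0 + Lp)
    scale = np.where(L > 0, Ld / np.clip(L, 1e-12, None), 0.0)
    return np.clip(pixels * scale[..., None], 0.0, 1.0)


def encode_srgb(display_linear: np.ndarray) -> np.ndarray:
    """Display-linear [0,1] to 8-bit sRGB codes (piecewise standard curve)."""
    x = np.clip(np.asarray(display_linear, dtype=np.float64), 0.0, 1.0)
    v = np.where(x <= 0.0031308, 12.92 * x, 1.055 * x ** (1 / 2.4) - 0.055)
    return np.round(v * 255.0).astype(np.uint8)

def decode_srgb(srgb: np.ndarray) -> np.ndarray:
    """8-bit sRGB codes (or floats in [0,1]) back to display-linear."""
    v = np.asarray(srgb, dtype=np.float64)
    if np.issubdtype(np.asarray(srgb).dtype, np.integer):
        v = v / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def display_luminance(display_linear: np.ndarray,
                      display: DisplayModel = DisplayModel()) -> np.ndarray:
    """Map display-linear values in [0,1] to emitted luminance in cd/m².

    luminance = black_level + (peak - black) * Y with Y the Rec.709 luminance
    of the display-linear image (pass-through for single-channel input).
    """
    x = np.asarray(display_linear, dtype=np.float64)
    if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
        raise ValueError("display-linear input must lie in [0, 1]")
    Y = luminance_709(x) if (x.ndim == 3 and x.shape[-1] == 3) else x
    return display.black_level + (display.peak_luminance - display.black_level) * np.clip(Y, 0, 1)
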