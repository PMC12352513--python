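"""End-to-end orchestration: render -> metrics -> vdp -> simulate -> analyse.

``run_pipeline`` executes the whole study on a synthetic factorial design:
it renders matched low/high-roughness image pairs, computes the specular
metrics and the visible-differences score per pair, simulates quadruplet
observers whose latent discriminabilities follow the vdp scores, applies the
behavioural gates, correlates metrics with pooled behaviour, and runs the
factor-importance analysis.  A manifest records seeds, parameters and
per-stage outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, factors, specular_metrics, synthetic_data, vdp_lite
from .io import write_json, write_trials_csv
from .render import (DisplayModel, ToneMapParams, decode_srgb, display_luminance,
                     encode_srgb, render_scene, tonemap_reinhard)

logger = logging.getLogger("glossjnd")

__all__ = ["PipelineConfig", "run_pipeline", "score_scene_pairs"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; round-trips losslessly through dict."""

    n_shapes: int = 3
    n_lights: int = 3
    n_viewpoints: int = 3
    image_size: int = 96
    roughness_pair: tuple[float, float] = synthetic_data.ALPHA_PAIR
    k: float = 0.0
    band_centers: tuple[float, ...] = (1, 2, 4, 8, 16, 32)
    tone: ToneMapParams = field(default_factory=ToneMapParams)
    display: DisplayModel = field(default_factory=DisplayModel)
    vdp: vdp_lite.VDPConfig = field(default_factory=vdp_lite.VDPConfig)
    n_observers: int = 15
    n_reps: int = 6
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _calibrated_luminances(scene, tone: ToneMapParams, display: DisplayModel):
    """Render full and diffuse-only components and carry both through
    tone mapping -> sRGB -> display calibration to luminance in cd/m².

    The same tone-map scale (from the full image) is applied to the diffuse
    render so the two stay mutually consistent for diffuse removal.
    """
    full = render_scene(scene, "full")
    diffuse = render_scene(scene, "diffuse_only")
    ldr_full = tonemap_reinhard(full, tone)
    # reuse the full image's log-average so subtraction stays meaningful
    from .render import luminance_709
    L = luminance_709(full.pixels)
    log_mean = float(np.exp(np.mean(np.log(L + 1e-9)))) if np.any(L > 0) else 1.0
    Ld = tone.key * luminance_709(diffuse.pixels) / log_mean
    Ld = Ld / (1.0 + Ld)
    scaleL = luminance_709(diffuse.pixels)
    scale = np.where(scaleL > 0, Ld / np.clip(scaleL, 1e-12, None), 0.0)
    ldr_diff = np.clip(diffuse.pixels * scale[..., None], 0, 1)

    lum_full = display_luminance(decode_srgb(encode_srgb(ldr_full)), display)
    lum_diff = display_luminance(decode_srgb(encode_srgb(ldr_diff)), display)
    return lum_full, lum_diff, full.mask


def score_scene_pairs(pairs, cfg: PipelineConfig) -> pd.DataFrame:
    """Per scene pair: specular-metric predictors and vdp scores."""
    mcfg = specular_metrics.MetricConfig(band_centers=cfg.band_centers)
    rows = []
    for i, (low, high) in enumerate(pairs):
        lum_lo, dif_lo, mask = _calibrated_luminances(low, cfg.tone, cfg.display)
        lum_hi, dif_hi, _ = _calibrated_luminances(high, cfg.tone, cfg.display)
        mv = specular_metrics.metric_vector_for_pair(
            lum_lo, dif_lo, lum_hi, dif_hi, mask, cfg.k, mcfg)
        pmap = vdp_lite.predict(lum_lo, lum_hi, cfg.vdp, mask=mask)
        mv.vdp_mean_full = pmap.pooled_mean_full
        mv.vdp_mean_object = pmap.pooled_mean_object
        mv.vdp_max = pmap.pooled_max
        row = {"scene": i, "shape": low.shape_id,
               "light": _light_label(low.lights),
               "viewpoint": f"e{low.viewpoint[0]:.0f}_a{low.viewpoint[1]:.0f}"}
        row.update(mv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _light_label(lights) -> str:
    return "+".join(
        f"{l.type}{np.round(np.mean(l.intensity), 2)}" for l in lights)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic study; returns the report bundle.

    When ``cfg.out_dir`` is set, scores, trials, frequencies and the manifest
    are written there as CSV/JSON.
    """
    rng = np.random.default_rng(cfg.seed)
    logger.info("stage render+score: %dx%dx%d design, %d px",
                cfg.n_shapes, cfg.n_lights, cfg.n_viewpoints, cfg.image_size)
    viewpoints = synthetic_data.sample_viewpoints_hemiicosphere(cfg.n_viewpoints)
    design = synthetic_data.FactorialDesign(
        shapes=synthetic_data.default_shapes(cfg.n_shapes),
        lights=synthetic_data.default_lights(cfg.n_lights),
        viewpoints=tuple(viewpoints),
        roughness_pair=cfg.roughness_pair,
        seed=cfg.seed,
    )
    pairs = synthetic_data.make_factorial_scenes(design, cfg.image_size)
    scores = score_scene_pairs(pairs, cfg)

    # simulate observers whose latent visibility follows the vdp score
    logger.info("stage simulate: %d observers x %d reps", cfg.n_observers, cfg.n_reps)
    d = scores["vdp_mean_full"].to_numpy()
    d_scaled = 4.0 * (d - d.mean()) / (d.std() + 1e-12)
    latents = synthetic_data.LatentVisibility(tuple(d_scaled), sigma=1.0)
    trials = pd.concat([
        synthetic_data.simulate_quadruplet_observer(
            latents, cfg.n_reps, participant_id=f"sim{i:02d}",
            seed=int(rng.integers(2**31)))
        for i in range(cfg.n_observers)
    ], ignore_index=True)

    logger.info("stage behavior: gates + pooling")
    gate = behavior.practice_gate_from_trials(trials)
    kept_ids = [p for p, ok in gate.items() if ok]
    main = trials[trials["participant_id"].isin(kept_ids)]
    freqs = behavior.selection_frequencies(main, n_scenes=len(pairs))
    report = behavior.exclude_outliers(freqs)
    pooled = behavior.pool_frequencies(freqs, ~report.excluded)

    corr_vdp = behavior.correlate(scores["vdp_mean_full"], pooled)
    corr_contrast = behavior.correlate(scores["combined_contrast"], pooled)
    weights, combo_r = behavior.fit_zscored_combo(
        scores[["combined_contrast", "coverage", "sharpness_tv"]], pooled)

    logger.info("stage factors: random-forest importance")
    imp = factors.rf_importance(scores[["light", "shape", "viewpoint"]],
                                scores["vdp_mean_full"].to_numpy(), seed=cfg.seed)

    bundle = {
        "config": cfg.to_dict(),
        "n_scene_pairs": len(pairs),
        "scores": scores,
        "trials": trials,
        "pooled_proportions": pooled,
        "exclusions": report,
        "correlation_vdp": corr_vdp,
        "correlation_contrast": corr_contrast,
        "cue_combo_weights": weights,
        "cue_combo_r": combo_r,
        "importance": imp,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out / "scores.csv", index=False)
        write_trials_csv(out / "trials.csv", trials)
        pd.DataFrame({"scene": np.arange(len(pooled)),
                      "proportion_chosen": pooled}).to_csv(
            out / "frequencies.csv", index=False)
        write_json(out / "exclusions.json", {
            "fence": report.fence,
            "mean_correlation": report.mean_correlation,
            "excluded": {p: bool(e) for p, e in
                         zip(report.participants, report.excluded)},
            "reasons": report.reasons,
        })
        write_json(out / "manifest.json", {
            "config": cfg.to_dict(),
            "n_scene_pairs": len(pairs),
            "correlation_vdp": corr_vdp,
            "correlation_contrast": corr_contrast,
            "cue_combo_r": combo_r,
            "importances": imp.importances,
        })
    return bundle
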