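"""Seeded generator of synthetic ureteroscopy-like videos with exact masks.

Each frame shows a brighter, reddish, textured ureter wall under radial
illumination falloff, with the lumen as a dark elliptical region whose
center drifts smoothly from frame to frame (consecutive frames differ
minimally, as in real endoscopic video).  The ground-truth mask is the exact
ellipse interior, so mask area has a closed form for oracle checks.

Artifacts mimic the endoscopic taxonomy: specular white highlights on the
wall, semi-transparent floating debris, defocus blur, a bleeding red tint,
and optional full-frame noise corruption of isolated center frames - the
last creating frames where only the temporal neighbors carry usable
information, the scenario multi-frame models exist for.

All randomness flows from one seed; per-video child seeds are spawned
independently of generation order, so any video can be regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .dataset import FrameDataset
from .errors import ConfigError
from .image_io import BinaryMask, Frame

DEFAULT_ARTIFACT_RATES: Dict[str, float] = {
    "specularity": 0.15,
    "debris": 0.10,
    "blur": 0.08,
    "bleeding_tint": 0.05,
    "center_frame_corruption": 0.0,
}

# video-to-patient layout mirroring a multi-video clinical collection:
# 6 patients, 11 videos, at least one patient contributing several videos
DEFAULT_PATIENT_LAYOUT = ("P1", "P1", "P2", "P2", "P3", "P4",
                          "P5", "P6", "P6", "P6", "P6")


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Generative parameters for one synthetic video."""

    frame_size: Tuple[int, int] = (64, 64)
    n_frames: int = 40
    trajectory_amplitude: float = 0.15   # lumen drift, fraction of min(p, q)
    angular_speed: float = 0.22          # radians per frame along the drift path
    lumen_radii: Tuple[float, float] = (11.0, 8.5)  # ellipse semi-axes, px
    radii_jitter: float = 0.05           # relative smooth per-frame jitter
    wall_texture_scale: float = 0.10     # multiplicative texture amplitude
    illumination_falloff: float = 0.55   # radial vignetting strength
    lumen_darkness: float = 0.15         # interior intensity multiplier
    artifact_rates: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES))
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        p, q = self.frame_size
        if self.n_frames < 1:
            raise ConfigError("n_frames must be at least 1")
        if p < 8 or q < 8:
            raise ConfigError("frame_size must be at least 8 x 8")
        if max(self.lumen_radii) >= min(p, q) / 2:
            raise ConfigError("lumen radii must be below min(p, q)/2")
        rates = dict(DEFAULT_ARTIFACT_RATES)
        rates.update(self.artifact_rates)
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"artifact rate {name!r} must lie in [0, 1]")
        object.__setattr__(self, "artifact_rates", rates)
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")


def _ellipse_mask(p, q, cx, cy, a, b) -> np.ndarray:
    yy, xx = np.mgrid[0:p, 0:q]
    return ((((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0).astype(np.uint8)


def _smooth_noise(rng, p, q, sigma_px) -> np.ndarray:
    field_ = rng.standard_normal((p, q))
    field_ = ndimage.gaussian_filter(field_, sigma_px)
    scale = field_.std()
    return field_ / scale if scale > 0 else field_


def generate_video(params: SyntheticSceneParams, video_id: str = "video0",
                   patient_id: str = "P1", return_flags: bool = False):
    """Render one synthetic video; deterministic in ``params.seed``.

    Returns ``(frames, masks)`` (and per-frame artifact flag dicts when
    ``return_flags`` is set).  Masks are the exact ellipse interiors; in
    every clean frame the lumen interior's mean intensity is strictly below
    the wall's.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    p, q = params.frame_size
    rates = params.artifact_rates

    base_color = np.clip(np.array([0.70, 0.42, 0.38])
                         + rng.uniform(-0.06, 0.06, 3), 0.05, 0.95)
    texture = _smooth_noise(rng, p, q, sigma_px=max(2.0, min(p, q) / 16))
    amp = params.trajectory_amplitude * min(p, q)
    phase = rng.uniform(0, 2 * np.pi, 2)
    speed2 = params.angular_speed * rng.uniform(0.6, 0.9)
    jitter_phase = rng.uniform(0, 2 * np.pi, 2)

    # isolated corrupted centers: never adjacent, never the video's edges
    corrupt = np.zeros(params.n_frames, dtype=bool)
    draws = rng.random(params.n_frames)
    for t in range(1, params.n_frames - 1):
        if draws[t] < rates["center_frame_corruption"] and not corrupt[t - 1]:
            corrupt[t] = True

    frames, masks, flags = [], [], []
    yy, xx = np.mgrid[0:p, 0:q]
    for t in range(params.n_frames):
        cx = q / 2 + amp * np.cos(params.angular_speed * t + phase[0])
        cy = p / 2 + amp * np.sin(speed2 * t + phase[1])
        ja = 1.0 + params.radii_jitter * np.sin(0.7 * t + jitter_phase[0])
        jb = 1.0 + params.radii_jitter * np.sin(0.9 * t + jitter_phase[1])
        a, b = params.lumen_radii[0] * ja, params.lumen_radii[1] * jb
        mask = _ellipse_mask(p, q, cx, cy, a, b)

        # wall shading: texture * vignetting centered on the lumen
        d2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (max(p, q) ** 2 / 2)
        illum = np.clip(1.0 - params.illumination_falloff * d2, 0.15, 1.0)
        shade = illum * (1.0 + params.wall_texture_scale * texture)
        img = base_color[None, None, :] * shade[:, :, None]

        # dark lumen with a soft rim but an exact analytic mask
        e = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
        rim = np.clip((e - 0.75) / 0.55, 0.0, 1.0)  # 0 deep inside, 1 outside
        dark = params.lumen_darkness + (1 - params.lumen_darkness) * rim
        img = img * dark[:, :, None]

        frame_flags = {k: False for k in rates}
        if rng.random() < rates["specularity"]:
            frame_flags["specularity"] = True
            for _ in range(rng.integers(1, 4)):
                sx, sy = rng.uniform(0, q), rng.uniform(0, p)
                if mask[min(int(sy), p - 1), min(int(sx), q - 1)]:
                    continue  # highlights live on the wall, not in the lumen
                r2 = (xx - sx) ** 2 + (yy - sy) ** 2
                blob = np.exp(-r2 / (2 * rng.uniform(1.0, 2.5) ** 2))
                blob *= 1.0 - mask  # keep the lumen interior dark
                img = img + 0.9 * blob[:, :, None]
        if rng.random() < rates["debris"]:
            frame_flags["debris"] = True
            dx, dy = rng.uniform(0, q), rng.uniform(0, p)
            r2 = (xx - dx) ** 2 + (yy - dy) ** 2
            blob = np.exp(-r2 / (2 * rng.uniform(2.0, 4.0) ** 2))
            tint = rng.uniform(0.3, 0.6, 3)
            img = img * (1 - 0.6 * blob[:, :, None]) \
                + 0.6 * blob[:, :, None] * tint[None, None, :]
        if rng.random() < rates["bleeding_tint"]:
            frame_flags["bleeding_tint"] = True
            img = img * np.array([1.0, 0.55, 0.55])[None, None, :] \
                + np.array([0.12, 0.0, 0.0])[None, None, :]
        if rng.random() < rates["blur"]:
            frame_flags["blur"] = True
            img = ndimage.gaussian_filter(img, (1.2, 1.2, 0))
        if params.noise_sigma > 0:
            img = img + rng.normal(0, params.noise_sigma, img.shape)
        if corrupt[t]:
            frame_flags["center_frame_corruption"] = True
            img = rng.uniform(0.0, 1.0, (p, q, 3))  # frame content destroyed
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        frames.append(Frame(img, t=t, video_id=video_id, patient_id=patient_id))
        masks.append(BinaryMask(mask, t=t, video_id=video_id))
        flags.append(frame_flags)
    if return_flags:
        return frames, masks, flags
    return frames, masks


def _vary_params(template: SyntheticSceneParams, child_seed: int,
                 rng: np.random.Generator) -> SyntheticSceneParams:
    """Per-video diversity: jitter radii, falloff and artifact rates within
    moderate ranges around the template."""
    a, b = template.lumen_radii
    radii = (a * rng.uniform(0.85, 1.15), b * rng.uniform(0.85, 1.15))
    limit = min(template.frame_size) / 2 - 1
    radii = (min(radii[0], limit), min(radii[1], limit))
    rates = {k: float(np.clip(v * rng.uniform(0.5, 1.5), 0, 1))
             if k != "center_frame_corruption" else v
             for k, v in template.artifact_rates.items()}
    return replace(template, lumen_radii=radii, artifact_rates=rates,
                   illumination_falloff=float(np.clip(
                       template.illumination_falloff * rng.uniform(0.85, 1.15),
                       0.0, 0.9)),
                   seed=child_seed)


def generate_dataset(n_videos: int = 11, frames_per_video: int = 40,
                     params: SyntheticSceneParams | None = None,
                     seed: int = 0,
                     patient_layout: Tuple[str, ...] | None = None
                     ) -> FrameDataset:
    """Generate a multi-patient fixture dataset.

    Videos are grouped into synthetic patients (default layout: 6 patients
    over 11 videos, several patients contributing more than one video); each
    video gets its own appearance parameters drawn around the template, and
    its own child seed, so any video regenerates identically in isolation.
    """
    if n_videos < 1:
        raise ConfigError("n_videos must be at least 1")
    template = params or SyntheticSceneParams(n_frames=frames_per_video)
    template = replace(template, n_frames=frames_per_video)
    if patient_layout is None:
        if n_videos == len(DEFAULT_PATIENT_LAYOUT):
            patient_layout = DEFAULT_PATIENT_LAYOUT
        else:
            n_pat = max(1, min(6, (n_videos + 1) // 2))
            patient_layout = tuple(f"P{1 + i % n_pat}" for i in range(n_videos))
    if len(patient_layout) != n_videos:
        raise ConfigError("patient_layout length must equal n_videos")

    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n_videos)]
    frames, masks, pids, vids, ts, corr = [], [], [], [], [], []
    for v in range(n_videos):
        vrng = np.random.default_rng(child_seeds[v])
        vparams = _vary_params(template, child_seeds[v], vrng)
        vid, pid = f"video{v}", patient_layout[v]
        fs, ms, fl = generate_video(vparams, vid, pid, return_flags=True)
        for f, m, fg in zip(fs, ms, fl):
            frames.append(f.pixels)
            masks.append(m.pixels)
            pids.append(pid)
            vids.append(vid)
            ts.append(f.t)
            corr.append(fg["center_frame_corruption"])
    return FrameDataset(np.stack(frames), np.stack(masks),
                        np.array(pids, dtype=object),
                        np.array(vids, dtype=object),
                        np.array(ts), np.array(corr))
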