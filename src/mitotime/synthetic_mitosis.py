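"""Synthetic single-cell mitosis time-lapse generator.

Produces 2D+t grayscale sequences of one tracked cell centered in the crop,
with per-frame stage labels and binary center-cell masks, emulating the
structure of fluorescently labeled chromatin (H2B marker) in live-cell
imaging: a large soft-textured interphase nucleus, chromatin condensation
at mitotic entry, a compact prometaphase mass, a metaphase plate, two
separating anaphase masses, and decondensing daughter nuclei that recover
an interphase-like appearance 15-20 frames after mitotic exit.  Off-center
distractor nuclei and Gaussian imaging noise provide clutter; the
center-cell mask never covers a distractor.

The rendering is parametric-geometric (soft-edged ellipses, condensation
speckles, smooth keyframe interpolation between stage appearances), not a
physics simulation.  Two properties are deliberate:

* stage transitions are gradual, so single frames near a boundary are
  genuinely ambiguous;
* recovered post-mitotic frames are rendered with the *same* appearance
  model as interphase, so in the 3-class scheme (where they keep the
  post-mitosis label) they are distinguishable only through temporal
  context.

Determinism: every sequence draws from an independent stream spawned from
the master seed (``SeedSequence(seed, spawn_key=(index,))``), so a dataset
is bit-reproducible and independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "THREE_CLASS_NAMES",
    "SIX_CLASS_NAMES",
    "SimConfig",
    "StageSchedule",
    "SyntheticSequence",
    "DatasetSplit",
    "sample_schedule",
    "render_frame",
    "simulate_sequence",
    "generate_dataset",
    "write_sequence",
    "read_sequence",
    "write_dataset",
    "read_dataset",
]

THREE_CLASS_NAMES = ("interphase", "mitosis", "post_mitosis")
SIX_CLASS_NAMES = ("interphase", "prophase", "prometaphase", "metaphase",
                   "anaphase", "telophase")

_BACKGROUND = 30.0


def _default_ranges(mode: str, sequence_length: int) -> dict[str, tuple[int, int]]:
    # Interphase is listed for completeness; its duration is adjusted to
    # make the stage durations sum to the sequence length.  Ranges scale
    # proportionally for shorter sequences.
    if mode == "three_class":
        if sequence_length >= 60:  # 90-frame regime
            return {"interphase": (20, 40), "mitosis": (10, 20),
                    "post_mitosis": (35, 55)}
        f = sequence_length / 30.0  # desk regime reference
        scaled = lambda lo, hi, floor: (max(floor, round(lo * f)),
                                        max(floor, round(lo * f), round(hi * f)))
        return {"interphase": scaled(3, 12, 2), "mitosis": scaled(4, 7, 2),
                "post_mitosis": scaled(14, 19, 3)}
    f = sequence_length / 40.0  # reference six-class regime length
    scaled = lambda lo, hi, floor: (max(floor, round(lo * f)),
                                    max(floor, round(lo * f), round(hi * f)))
    return {"interphase": scaled(8, 14, 2), "prophase": scaled(3, 6, 1),
            "prometaphase": scaled(3, 6, 1), "metaphase": scaled(4, 8, 2),
            "anaphase": scaled(3, 6, 1), "telophase": scaled(6, 10, 2)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``recovery_onset`` is the (inclusive) range of post-mitosis frame
    offsets at which daughter morphology reverts to interphase-like
    appearance; its default mirrors the 15-20 frame recovery window of the
    90-frame regime and scales to (6, 9) in the 30-frame desk regime.
    """

    mode: str = "three_class"
    frame_size: int = 96
    sequence_length: int | None = None
    stage_duration_ranges: dict[str, tuple[int, int]] | None = None
    n_distractors: tuple[int, int] = (1, 3)
    noise_sd: float = 6.0
    recovery_onset: tuple[int, int] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("three_class", "six_class"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.frame_size < 32:
            raise ValueError("frame_size must be >= 32")
        if self.sequence_length is None:
            object.__setattr__(self, "sequence_length",
                               90 if self.mode == "three_class" else 40)
        if self.stage_duration_ranges is None:
            object.__setattr__(self, "stage_duration_ranges",
                               _default_ranges(self.mode, self.sequence_length))
        if self.recovery_onset is None:
            object.__setattr__(self, "recovery_onset",
                               (15, 20) if self.sequence_length >= 60 else (6, 9))
        for name, (lo, hi) in self.stage_duration_ranges.items():
            if lo > hi or lo < 1:
                raise ValueError(f"empty duration range for {name}: ({lo},{hi})")
        if set(self.stage_duration_ranges) != set(self.stage_names):
            raise ValueError("stage_duration_ranges must cover every stage")

    @property
    def stage_names(self) -> tuple[str, ...]:
        return THREE_CLASS_NAMES if self.mode == "three_class" else SIX_CLASS_NAMES

    @property
    def n_class(self) -> int:
        return len(self.stage_names)

    @classmethod
    def desk(cls, mode: str = "three_class", **kw) -> "SimConfig":
        """Desk-scale regime: 64x64 frames, 30-frame sequences."""
        kw.setdefault("frame_size", 64)
        kw.setdefault("sequence_length", 30 if mode == "three_class" else 40)
        return cls(mode=mode, **kw)


@dataclass(frozen=True)
class StageSchedule:
    """Per-frame 1-based stage labels (non-decreasing, contiguous runs in
    the fixed biological order)."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if np.any(np.diff(labels) < 0):
            raise ValueError("stage labels must be non-decreasing")
        if np.any(np.diff(labels) > 1):
            raise ValueError("stages must appear in order without gaps")

    def __len__(self) -> int:
        return len(self.labels)

    def stage_start(self, stage: int) -> int | None:
        idx = np.flatnonzero(self.labels == stage)
        return int(idx[0]) if idx.size else None


@dataclass
class SyntheticSequence:
    """Frames (T, H, W) uint8, masks (T, H, W) bool, schedule, metadata."""

    frames: np.ndarray
    masks: np.ndarray
    schedule: StageSchedule
    meta: dict

    def __post_init__(self):
        if not (len(self.frames) == len(self.masks) == len(self.schedule)):
            raise ValueError("frames, masks and labels must share a length")

    @property
    def labels(self) -> np.ndarray:
        return self.schedule.labels

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DatasetSplit:
    train: list[SyntheticSequence]
    test: list[SyntheticSequence]
    ratio: float


# ---------------------------------------------------------------------------
# schedule sampling
# ---------------------------------------------------------------------------

def sample_schedule(config: SimConfig, rng: np.random.Generator) -> StageSchedule:
    """Draw stage durations uniformly from the configured ranges, then
    adjust the interphase run so the total equals the sequence length."""
    names = config.stage_names
    ranges = config.stage_duration_ranges
    durations = {n: int(rng.integers(lo, hi + 1)) for n, (lo, hi) in
                 ((n, ranges[n]) for n in names)}
    others_min = sum(ranges[n][0] for n in names[1:])
    if config.sequence_length < others_min + 1:
        raise ValueError(
            f"sequence_length {config.sequence_length} is shorter than the "
            f"minimum stage durations ({others_min} + 1 interphase frame)")
    durations[names[0]] = config.sequence_length - sum(
        durations[n] for n in names[1:])
    while durations[names[0]] < 1:
        # shrink the longest later stage until interphase fits
        longest = max(names[1:], key=lambda n: durations[n] - ranges[n][0])
        durations[longest] -= 1
        durations[names[0]] += 1
    labels = np.concatenate([
        np.full(durations[n], i + 1, dtype=int) for i, n in enumerate(names)])
    return StageSchedule(labels)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class _Scene:
    """Per-sequence appearance parameters (fixed across frames)."""

    inter_radii: tuple[float, float]
    angle: float
    intensity: float
    division_axis: float
    recovery_onset: int
    texture: np.ndarray          # multiplicative smooth field, full frame
    speckle_offsets: np.ndarray  # (K, 2) unit-disc positions
    distractors: list[dict]


def _smooth_field(rng: np.random.Generator, size: int, amp: float) -> np.ndarray:
    coarse = rng.uniform(1.0 - amp, 1.0 + amp, (6, 6))
    idx = np.linspace(0, 5, size)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    i0, j0 = np.floor(ii).astype(int), np.floor(jj).astype(int)
    i1, j1 = np.minimum(i0 + 1, 5), np.minimum(j0 + 1, 5)
    fi, fj = ii - i0, jj - j0
    return (coarse[i0, j0] * (1 - fi) * (1 - fj) + coarse[i1, j0] * fi * (1 - fj)
            + coarse[i0, j1] * (1 - fi) * fj + coarse[i1, j1] * fi * fj)


def _sample_scene(config: SimConfig, rng: np.random.Generator) -> _Scene:
    s = config.frame_size / 96.0
    n_lo, n_hi = config.n_distractors
    n_dis = int(rng.integers(n_lo, n_hi + 1))
    min_dist = 0.30 * config.frame_size
    distractors = []
    for _ in range(n_dis):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(min_dist, 0.46 * config.frame_size)
        distractors.append({
            "angle": ang,
            "dist": dist,
            "radii": (rng.uniform(7, 10) * s, rng.uniform(6, 8) * s),
            "theta": rng.uniform(0, np.pi),
            "intensity": rng.uniform(80, 110),
            "velocity": rng.uniform(-0.15, 0.15, 2) * s,
            "min_dist": min_dist,
        })
    lo, hi = config.recovery_onset
    return _Scene(
        inter_radii=(rng.uniform(12, 15) * s, rng.uniform(9, 12) * s),
        angle=rng.uniform(0, np.pi),
        intensity=rng.uniform(110, 140),
        division_axis=rng.uniform(0, 2 * np.pi),
        recovery_onset=int(rng.integers(lo, hi + 1)),
        texture=_smooth_field(rng, config.frame_size, 0.15),
        speckle_offsets=rng.uniform(-0.75, 0.75, (10, 2)),
        distractors=distractors,
    )


def _draw_nucleus(canvas, cx, cy, a, b, theta, intensity, texture,
                  speckles=None, speckle_amp=0.0):
    """Soft-edged textured ellipse; returns its boolean footprint."""
    size = canvas.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    q = u * u + v * v
    profile = np.clip((1.0 - q) / 0.45, 0.0, 1.0) ** 0.5
    field = intensity * profile * texture
    if speckles is not None and speckle_amp > 0:
        sp = np.zeros_like(canvas)
        r = 0.16 * (a + b)
        for ox, oy in speckles:
            px, py = cx + ox * a * 0.8, cy + oy * b * 0.8
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            sp += np.exp(-d2 / (2 * r * r))
        field *= 1.0 + speckle_amp * np.clip(sp, 0, 1.2)
    inside = q <= 1.0
    field *= inside
    np.maximum(canvas, field, out=canvas)
    return inside


def _stage_appearance(config: SimConfig, scene: _Scene, stage_name: str,
                      progress: float, post_frame: int):
    """Geometry/intensity keyframes for the tracked cell at one frame.

    Returns (radii, theta, intensity, speckle_amp, center_offset,
    sister) where sister is None or a dict for the second chromatin mass.
    """
    s = config.frame_size / 96.0
    a0, b0 = scene.inter_radii
    inter = dict(radii=(a0, b0), theta=scene.angle, intensity=scene.intensity,
                 speckle=0.12, offset=(0.0, 0.0), sister=None)
    pro = dict(radii=(0.8 * a0, 0.8 * b0), theta=scene.angle,
               intensity=150.0, speckle=0.55, offset=(0.0, 0.0), sister=None)
    prometa = dict(radii=(7.5 * s, 7.0 * s), theta=scene.angle,
                   intensity=200.0, speckle=0.35, offset=(0.0, 0.0), sister=None)
    meta = dict(radii=(9.5 * s, 4.0 * s), theta=scene.division_axis + np.pi / 2,
                intensity=215.0, speckle=0.2, offset=(0.0, 0.0), sister=None)

    def lerp(k0, k1, f):
        f = float(np.clip(f, 0.0, 1.0))
        out = dict(
            radii=tuple((1 - f) * np.array(k0["radii"]) + f * np.array(k1["radii"])),
            theta=(1 - f) * k0["theta"] + f * k1["theta"],
            intensity=(1 - f) * k0["intensity"] + f * k1["intensity"],
            speckle=(1 - f) * k0["speckle"] + f * k1["speckle"],
            offset=k0["offset"], sister=None)
        return out

    if stage_name == "interphase":
        return inter
    if stage_name == "prophase":
        return lerp(inter, pro, 0.4 + 0.6 * progress)
    if stage_name == "prometaphase":
        return lerp(pro, prometa, 0.5 + 0.5 * progress)
    if stage_name == "metaphase":
        return lerp(prometa, meta, 0.5 + 0.5 * progress)
    if stage_name == "mitosis":
        # 3-class scheme: prophase -> prometaphase -> metaphase inside one run
        if progress < 0.35:
            return lerp(inter, pro, 0.3 + 2 * progress)
        if progress < 0.65:
            return lerp(pro, prometa, (progress - 0.35) / 0.3)
        return lerp(prometa, meta, (progress - 0.65) / 0.35)

    # anaphase / telophase / 3-class post-mitosis: two masses, the tracked
    # one drifting back to the crop center over ~3 frames
    phi = scene.division_axis
    if stage_name == "anaphase":
        d = (3.0 + 5.0 * progress) * s
        blob = dict(radii=(6.5 * s, 5.5 * s), theta=phi, intensity=205.0,
                    speckle=0.3,
                    offset=(0.5 * d * np.cos(phi), 0.5 * d * np.sin(phi)),
                    sister=dict(radii=(6.5 * s, 5.5 * s), theta=phi,
                                intensity=200.0,
                                offset=(-0.5 * d * np.cos(phi),
                                        -0.5 * d * np.sin(phi))))
        return blob

    # telophase (6-class) or post_mitosis (3-class), indexed by post_frame
    p = post_frame
    recenter = max(0.0, 1.0 - p / 3.0)
    sep = min(4.0 + 2.2 * p, 17.0) * s
    sister_off = (-sep * np.cos(phi), -sep * np.sin(phi))
    track_off = (0.5 * sep * recenter * np.cos(phi),
                 0.5 * sep * recenter * np.sin(phi))
    if config.mode == "three_class" and p < 2:
        # first post-mitosis frames look like late anaphase
        base = dict(radii=(6.5 * s, 5.5 * s), theta=phi, intensity=205.0,
                    speckle=0.3, offset=track_off, sister=None)
    elif p >= scene.recovery_onset:
        base = dict(inter)  # recovered: interphase-like by construction
    else:
        q = p / scene.recovery_onset
        grown = dict(radii=(6.5 * s, 5.5 * s), theta=phi, intensity=205.0,
                     speckle=0.45, offset=(0, 0), sister=None)
        base = lerp(grown, inter, q)
        base["theta"] = (1 - q) * phi + q * scene.angle
        base["offset"] = track_off
    sis_int = max(60.0, 200.0 - 10.0 * p)
    base["sister"] = dict(radii=(6.5 * s, 6.0 * s), theta=phi,
                          intensity=sis_int, offset=sister_off)
    base["offset"] = track_off
    return base


def render_frame(schedule: StageSchedule, t: int, config: SimConfig,
                 rng: np.random.Generator, scene: _Scene | None = None):
    """Render frame ``t`` of a schedule: returns (image uint8, mask bool).

    The per-sequence scene (cell geometry, distractor layout, recovery
    onset) is drawn from ``rng`` if not supplied; pass the same scene for
    every frame of one sequence to obtain a coherent movie.
    """
    if not 0 <= t < len(schedule):
        raise IndexError(f"frame index {t} outside 0..{len(schedule) - 1}")
    if scene is None:
        scene = _sample_scene(config, rng)
    size = config.frame_size
    center = (size - 1) / 2.0
    stage = int(schedule.labels[t])
    names = config.stage_names
    name = names[stage - 1]
    run = np.flatnonzero(schedule.labels == stage)
    progress = (t - run[0]) / max(len(run) - 1, 1)
    post_start = schedule.stage_start(len(names))  # final stage of the scheme
    post_frame = t - post_start if (post_start is not None and t >= post_start) else 0
    if config.mode == "six_class" and name == "telophase":
        post_frame = t - schedule.stage_start(6)
    app = _stage_appearance(config, scene, name, progress, post_frame)

    canvas = np.zeros((size, size), dtype=float)
    footprints = np.zeros((size, size), dtype=bool)
    # distractor nuclei (never under the center-cell mask by construction)
    for d in scene.distractors:
        pos = np.array([center + d["dist"] * np.cos(d["angle"]),
                        center + d["dist"] * np.sin(d["angle"])])
        pos = pos + d["velocity"] * t
        off = pos - center
        dist = np.hypot(*off)
        if dist < d["min_dist"]:  # clamp drift so it never nears the center
            pos = center + off / dist * d["min_dist"]
        fp = _draw_nucleus(canvas, pos[0], pos[1], d["radii"][0], d["radii"][1],
                           d["theta"], d["intensity"], scene.texture)
        footprints |= fp
    # sister chromatin mass / departing daughter
    if app.get("sister") is not None:
        sis = app["sister"]
        fp = _draw_nucleus(canvas, center + sis["offset"][0],
                           center + sis["offset"][1], sis["radii"][0],
                           sis["radii"][1], sis["theta"], sis["intensity"],
                           scene.texture, scene.speckle_offsets, 0.3)
        footprints |= fp
    # tracked center cell (drawn last; the mask is its footprint alone)
    mask = _draw_nucleus(canvas, center + app["offset"][0],
                         center + app["offset"][1], app["radii"][0],
                         app["radii"][1], app["theta"], app["intensity"],
                         scene.texture, scene.speckle_offsets, app["speckle"])
    footprints |= mask
    image = _BACKGROUND + canvas
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)
    return image, mask


def simulate_sequence(config: SimConfig, rng: np.random.Generator,
                      index: int = 0) -> SyntheticSequence:
    """Sample a schedule and scene, then render every frame."""
    schedule = sample_schedule(config, rng)
    scene = _sample_scene(config, rng)
    frames, masks = [], []
    for t in range(len(schedule)):
        img, msk = render_frame(schedule, t, config, rng, scene)
        frames.append(img)
        masks.append(msk)
    meta = {"mode": config.mode, "frame_size": config.frame_size,
            "sequence_length": config.sequence_length,
            "recovery_onset": scene.recovery_onset, "index": index,
            "noise_sd": config.noise_sd}
    return SyntheticSequence(np.stack(frames), np.stack(masks), schedule, meta)


# ---------------------------------------------------------------------------
# dataset generation and on-disk layout
# ---------------------------------------------------------------------------

def generate_dataset(n_sequences: int, config: SimConfig, seed: int,
                     ratio: float = 0.85) -> DatasetSplit:
    """Generate ``n_sequences`` independent sequences and split them
    train/test (|train| = round(ratio * n)).

    Each sequence gets its own counter-derived RNG stream, so the dataset
    is reproducible regardless of generation order.
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences to split")
    seqs = []
    for i in range(n_sequences):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        seqs.append(simulate_sequence(config, rng, index=i))
    n_train = round(ratio * n_sequences)
    return DatasetSplit(train=seqs[:n_train], test=seqs[n_train:], ratio=ratio)


def write_sequence(seq: SyntheticSequence, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "frames.tif", seq.frames)
    tifffile.imwrite(directory / "masks.tif",
                     seq.masks.astype(np.uint8) * 255)
    pd.DataFrame({"frame_index": np.arange(len(seq)),
                  "stage_label": seq.labels}).to_csv(
        directory / "labels.csv", index=False)
    (directory / "meta.json").write_text(json.dumps(seq.meta, indent=2))


def read_sequence(directory) -> SyntheticSequence:
    directory = Path(directory)
    frames = tifffile.imread(directory / "frames.tif")
    masks = tifffile.imread(directory / "masks.tif") > 0
    labels = pd.read_csv(directory / "labels.csv")["stage_label"].to_numpy()
    meta_path = directory / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SyntheticSequence(frames, masks, StageSchedule(labels), meta)


def write_dataset(split: DatasetSplit, directory) -> None:
    directory = Path(directory)
    for part in ("train", "test"):
        for i, seq in enumerate(getattr(split, part)):
            write_sequence(seq, directory / part / f"seq_{i:04d}")
    (directory / "split.json").write_text(
        json.dumps({"ratio": split.ratio, "n_train": len(split.train),
                    "n_test": len(split.test)}))


def read_dataset(directory) -> DatasetSplit:
    directory = Path(directory)
    info = json.loads((directory / "split.json").read_text())
    parts = {}
    for part in ("train", "test"):
        dirs = sorted((directory / part).iterdir())
        parts[part] = [read_sequence(d) for d in dirs if d.is_dir()]
    return DatasetSplit(train=parts["train"], test=parts["test"],
                        ratio=info["ratio"])
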