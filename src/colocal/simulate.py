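"""Synthetic two-type imaging studies with a controllable co-localization
difference between groups.

Each image contains two cell types. Type A is a homogeneous Poisson
process whose expected count is drawn uniformly from ``cell_count_choices``
(independently per image).  The intensity for type B is the disc-kernel
density of the realised A pattern, renormalised to integrate to one over
the window and scaled by a second uniform draw from
``cell_count_choices``, so B cells cluster around A cells at the
subject's characteristic distance.  Each subject's co-localization scale
is a kernel bandwidth drawn once from Poisson(sigma) (group 1) or
Poisson(sigma + delta) (group 2, difference regime only); following the
usual kernel-smoothing convention the uniform disc is scaled so its
standard deviation equals the bandwidth, i.e. the disc radius is twice
the drawn bandwidth.  Sharing the bandwidth across a subject's images is
what induces subject-level correlation, the structure the
random-intercept model is designed for.

In the null regime both groups draw their radii from Poisson(sigma): the
groups are exchangeable and any detected difference is a false positive.
A larger disc spreads B more diffusely around A, weakening the measured
co-localization, so the difference regime shifts group 2's scores.

Randomness is organised as a splittable tree of ``numpy`` seed
sequences: study seed -> (subject-level stream, one stream per image),
and replicate r of a study collection uses ``SeedSequence((master_seed,
r, regime_tag))``, so every replicate and image is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CellImage, ImageSet, Window
from .spatial import DEFAULT_RADII

__all__ = ["SimConfig", "SimTruth", "simulate_study", "run_simulation_study",
           "SimStudyResult"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults describe a 1000 x 1000-unit image, 40 subjects split into
    two groups of 20, three images per subject, per-image expected cell
    counts uniform on {20, 40, ..., 400}, mean co-localization bandwidth
    sigma = 40 units and group shift delta = sigma / 3.
    """

    window: Window = Window(0.0, 1000.0, 0.0, 1000.0)
    n_subjects: int = 40
    images_per_subject: int = 3
    cell_count_choices: tuple[int, ...] = tuple(range(20, 401, 20))
    sigma: float = 40.0
    delta: float = 40.0 / 3.0
    count_multiplier: int = 1
    density_grid: int = 128

    def __post_init__(self):
        if self.sigma <= 0 or self.delta < 0:
            raise ValueError("sigma must be > 0 and delta >= 0")
        if min(self.cell_count_choices) < 1:
            raise ValueError("cell counts must be >= 1")
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ValueError("n_subjects must be even and >= 2 (two equal groups)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Read ``key = value`` lines; unknown keys error."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "window":
                kwargs["window"] = Window(*(float(v) for v in value.split(",")))
            elif key == "cell_count_choices":
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key in ("n_subjects", "images_per_subject", "count_multiplier",
                         "density_grid"):
                kwargs[key] = int(value)
            elif key in ("sigma", "delta"):
                kwargs[key] = float(value)
            else:
                raise ValueError(f"unknown simulator parameter {key!r}")
        return cls(**kwargs)


#: ratio of disc radius to kernel bandwidth: a uniform disc of radius R has
#: per-axis standard deviation R/2, so matching sd = bandwidth gives R = 2 sd.
DISC_RADIUS_PER_BANDWIDTH = 2.0


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    regime: str
    group_of: dict[str, int]  # subject -> 1 or 2
    bandwidth_of: dict[str, float]  # subject -> realised kernel bandwidth draw
    disc_radius_of: dict[str, float]  # subject -> disc radius (2 x bandwidth)
    counts: pd.DataFrame  # per image: realised n_A, n_B
    notes: list[str] = field(default_factory=list)


def _positive_poisson(rng: np.random.Generator, mean: float) -> int:
    """Poisson draw, redrawn while zero (a zero disc radius is degenerate)."""
    for _ in range(1000):
        v = int(rng.poisson(mean))
        if v > 0:
            return v
    raise RuntimeError(f"Poisson({mean}) kept returning 0")  # pragma: no cover


class _PixelMesh:
    """Pixel grid over the window, shared by all images of a study."""

    def __init__(self, win: Window, grid: int):
        self.gx = np.linspace(win.x_min, win.x_max, grid + 1)
        self.gy = np.linspace(win.y_min, win.y_max, grid + 1)
        cx = 0.5 * (self.gx[:-1] + self.gx[1:])
        cy = 0.5 * (self.gy[:-1] + self.gy[1:])
        self.pix_area = (self.gx[1] - self.gx[0]) * (self.gy[1] - self.gy[0])
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        self.centres = np.column_stack([xx.ravel(), yy.ravel()])
        self.shape = (grid, grid)
        from scipy.spatial import cKDTree

        self.tree = cKDTree(self.centres)


def _disc_density(ax: np.ndarray, ay: np.ndarray, radius: float,
                  mesh: _PixelMesh) -> np.ndarray:
    """Disc-kernel density of the A pattern at the pixel centres,
    renormalised to integrate to 1 over the window."""
    hits = mesh.tree.query_ball_point(np.column_stack([ax, ay]), radius)
    idx = np.concatenate([np.asarray(h, dtype=np.intp) for h in hits]) \
        if len(hits) else np.empty(0, dtype=np.intp)
    counts = np.bincount(idx, minlength=mesh.centres.shape[0])
    dens = counts.reshape(mesh.shape) / (np.pi * radius**2)
    total = dens.sum() * mesh.pix_area
    if total > 0:
        dens = dens / total
    return dens


def simulate_study(
    cfg: SimConfig = SimConfig(),
    regime: str = "null",
    seed: int | np.random.SeedSequence = 0,
) -> tuple[ImageSet, SimTruth]:
    """Generate one study (ImageSet plus ground truth).

    regime : "null" (both groups share the co-localization scale sigma)
        or "difference" (group 2 uses sigma + delta).
    """
    if regime not in ("null", "difference"):
        raise ValueError(f"unknown regime {regime!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_images = cfg.n_subjects * cfg.images_per_subject
    streams = ss.spawn(n_images + 1)
    subject_rng = np.random.default_rng(streams[0])

    half = cfg.n_subjects // 2
    subjects = [f"s{k + 1:03d}" for k in range(cfg.n_subjects)]
    group_of = {sid: (1 if k < half else 2) for k, sid in enumerate(subjects)}
    bandwidth_of: dict[str, float] = {}
    radius_of: dict[str, float] = {}
    for sid in subjects:
        mean = cfg.sigma
        if regime == "difference" and group_of[sid] == 2:
            mean = cfg.sigma + cfg.delta
        bandwidth_of[sid] = float(_positive_poisson(subject_rng, mean))
        radius_of[sid] = DISC_RADIUS_PER_BANDWIDTH * bandwidth_of[sid]

    choices = np.asarray(cfg.cell_count_choices, float) * cfg.count_multiplier
    win = cfg.window
    mesh = _PixelMesh(win, cfg.density_grid)
    s = ImageSet()
    truth_rows = []
    notes: list[str] = []
    img_index = 0
    for sid in subjects:
        for j in range(cfg.images_per_subject):
            rng = np.random.default_rng(streams[1 + img_index])
            img_index += 1
            iid = f"{sid}_img{j + 1}"
            c_a = float(rng.choice(choices))
            n_a = int(rng.poisson(c_a))
            ax = rng.uniform(win.x_min, win.x_max, n_a)
            ay = rng.uniform(win.y_min, win.y_max, n_a)

            c_b = float(rng.choice(choices))
            if n_a == 0:
                notes.append(f"{iid}: empty A pattern; B placed homogeneously")
                n_b = int(rng.poisson(c_b))
                bx = rng.uniform(win.x_min, win.x_max, n_b)
                by = rng.uniform(win.y_min, win.y_max, n_b)
            else:
                dens = _disc_density(ax, ay, radius_of[sid], mesh)
                gx, gy, pix_area = mesh.gx, mesh.gy, mesh.pix_area
                lam = c_b * dens * pix_area
                counts = rng.poisson(lam)
                n_b = int(counts.sum())
                ix, iy = np.nonzero(counts)
                reps = counts[ix, iy]
                x0 = np.repeat(gx[ix], reps)
                y0 = np.repeat(gy[iy], reps)
                bx = x0 + rng.uniform(0.0, gx[1] - gx[0], n_b)
                by = y0 + rng.uniform(0.0, gy[1] - gy[0], n_b)

            x = np.concatenate([ax, bx])
            y = np.concatenate([ay, by])
            marks = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
            s.add_image(
                CellImage(iid, x, y, marks, win),
                subject_id=sid,
                condition=f"group{group_of[sid]}",
            )
            truth_rows.append({"image_id": iid, "subject_id": sid,
                               "n_A": n_a, "n_B": n_b})

    truth = SimTruth(
        regime=regime,
        group_of=group_of,
        bandwidth_of=bandwidth_of,
        disc_radius_of=radius_of,
        counts=pd.DataFrame(truth_rows),
        notes=notes,
    )
    return s, truth


@dataclass
class SimStudyResult:
    """Paired null/difference p-value collections per analysis mode."""

    null_p: dict[str, np.ndarray]  # mode ("fitted"/"none") -> p-values
    diff_p: dict[str, np.ndarray]
    config: dict
    failures: int = 0
    failure_log: list[str] = field(default_factory=list)


def _analyse_replicate(
    study: ImageSet,
    radii: Sequence[float],
    correction: str,
    weight_modes: Sequence[str],
    model: str,
) -> dict[str, float]:
    """p-value of the A->B condition effect for each weighting mode,
    computing the score table once."""
    from .inference import CoLocModel

    m = CoLocModel(study, condition="condition", subject="subject_id",
                   types=["A", "B"], radii=radii, correction=correction)
    scores = m._scores()
    out: dict[str, float] = {}
    for mode in weight_modes:
        res = m.fit(weights=mode, model=model, scores=scores)
        row = [r for r in res.pair_results
               if r.type_i == "A" and r.type_j == "B"]
        out[mode] = float(row[0].p_raw)
    return out


def run_simulation_study(
    cfg: SimConfig = SimConfig(),
    n_null: int = 100,
    n_diff: int = 100,
    master_seed: int = 0,
    radii: Sequence[float] = DEFAULT_RADII,
    correction: str = "translation",
    weight_modes: Sequence[str] = ("fitted", "none"),
    model: str = "mixed",
    max_failure_fraction: float = 0.05,
    progress: bool = False,
) -> SimStudyResult:
    """Simulate ``n_null`` null and ``n_diff`` difference studies and run
    the full pipeline on each, collecting the A->B p-values per weighting
    mode.

    Replicate r of regime g is seeded by ``SeedSequence((master_seed, tag,
    r))`` with tag 0 for null and 1 for difference, so the two regimes and
    all replicates are independent and individually reproducible.
    """
    if n_null < 1 or n_diff < 1:
        raise ValueError("replicate counts must be >= 1")
    collections: dict[str, dict[str, list[float]]] = {
        "null": {m: [] for m in weight_modes},
        "difference": {m: [] for m in weight_modes},
    }
    failures: list[str] = []
    plan = [("null", 0, r) for r in range(n_null)] + [
        ("difference", 1, r) for r in range(n_diff)
    ]
    iterator = plan
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(plan, desc="replicates")
        except ImportError:
            pass
    for regime, tag, r in iterator:
        ss = np.random.SeedSequence((master_seed, tag, r))
        try:
            study, _ = simulate_study(cfg, regime=regime, seed=ss)
            ps = _analyse_replicate(study, radii, correction, weight_modes, model)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            failures.append(f"{regime} replicate {r}: {exc!r}")
            continue
        for mode, p in ps.items():
            collections[regime][mode].append(p)
    n_total = n_null + n_diff
    if len(failures) / n_total >= max_failure_fraction:
        raise RuntimeError(
            f"{len(failures)}/{n_total} replicates failed: {failures[:5]}"
        )
    return SimStudyResult(
        null_p={m: np.asarray(v) for m, v in collections["null"].items()},
        diff_p={m: np.asarray(v) for m, v in collections["difference"].items()},
        config={
            "cfg": cfg, "n_null": n_null, "n_diff": n_diff,
            "master_seed": master_seed, "radii": list(radii),
            "correction": correction, "model": model,
            "weight_modes": list(weight_modes),
        },
        failures=len(failures),
        failure_log=failures,
    )
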