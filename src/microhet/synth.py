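"""Synthetic-data generation for every pipeline stage.

Renders time-lapse image stacks of exponentially growing textured
microcolonies with exact ground truth, draws growth-rate mixtures with a
planted slow sub-population, builds whole planted deletion screens,
simulates branching populations that switch membrane-potential state,
and fabricates annotation tables and qPCR plates.  Everything is seeded:
identical spec + seed gives identical output.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .organelle import QpcrPlate, SwitchingModelParams

__all__ = [
    "ColonySpec",
    "MixtureSpec",
    "PlantedScreenSpec",
    "TimelapseResult",
    "SwitchingPopulation",
    "CATEGORIES",
    "WT_MIXTURE",
    "generate_timelapse",
    "grid_colony_specs",
    "generate_rate_mixture",
    "generate_switching_population",
    "generate_annotation",
    "generate_qpcr_plate",
    "generate_screen",
    "save_timelapse",
    "load_timelapse",
]

# Rendering constants.  Colony texture is a bright/dark checkerboard of
# amplitude TEXTURE_AMPLITUDE around the background mean.  The amplitude is
# many background s.d. for two reasons: the +/-2.2 s.d. pixel detector must
# keep firing late in the series when colony pixels inflate the whole-frame
# variance, and at the start of observation (tiny colony coverage, frame
# s.d. ~ background s.d.) even the small colony contribution to the frame
# variance must push the detection threshold clear of the Gaussian
# background's own 2.2-s.d. tail.
BACKGROUND_MEAN = 1000.0
TEXTURE_AMPLITUDE = 60.0


@dataclass(frozen=True)
class ColonySpec:
    """One rendered microcolony: geometry and its true growth law."""

    colony_id: int
    seed_position: tuple[int, int]  # (row, col)
    initial_area: int  # pixels
    true_rate: float  # h^-1
    lag_duration: float = 0.0  # h
    slowdown_onset: float | None = None  # h; area held constant afterwards
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_area <= 0:
            raise ValueError("initial_area must be > 0")
        if self.true_rate < 0:
            raise ValueError("true_rate must be >= 0")
        if self.lag_duration < 0:
            raise ValueError("lag_duration must be >= 0")

    def area_at(self, t_h: float) -> int:
        """True pixel area at time t: round(A0 * exp(rate * max(0, t - lag))),
        frozen once the slowdown onset (if any) has passed."""
        if self.slowdown_onset is not None:
            t_h = min(t_h, self.slowdown_onset)
        growth_time = max(0.0, t_h - self.lag_duration)
        return int(round(self.initial_area * math.exp(self.true_rate * growth_time)))


@dataclass(frozen=True)
class MixtureSpec:
    """Truncated-normal mixture of growth rates.

    ``components`` is a list of (weight, mean h^-1, sd h^-1); weights must
    sum to 1.  Negative draws are redrawn (truncation at 0).
    """

    components: tuple[tuple[float, float, float], ...]
    n_colonies: int
    rng_seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple(tuple(c) for c in self.components)
        object.__setattr__(self, "components", comps)
        w = [c[0] for c in comps]
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("component weights must be >= 0 and sum to 1")
        if any(c[2] < 0 for c in comps):
            raise ValueError("sd_rate must be >= 0")
        if self.n_colonies <= 0:
            raise ValueError("n_colonies must be > 0")


#: Wild-type microcolony growth-rate mixture: a fast bulk whose mode sits at
#: 0.407 h^-1 and a ~10% slow-growing sub-population.
WT_MIXTURE = ((0.9, 0.407, 0.02), (0.1, 0.15, 0.05))

#: Mutant phenotype categories used by the screen classifier.
CATEGORIES = (
    "no-change",
    "mode-only",
    "slow-down-only",
    "slow-up-only",
    "both-down",
    "mode-down-slow-up",
    "other",
)


@dataclass(frozen=True)
class PlantedScreenSpec:
    """A synthetic deletion screen with known per-strain phenotypes.

    Each strain gets ``replicates`` independent rate distributions drawn
    from the WT mixture modified by its planted category: ``mode_shift``
    moves the bulk mean, ``slow_up``/``slow_down`` change the slow-fraction
    weight (percentage points).
    """

    n_strains: int = 21
    replicates: int = 3
    n_per_replicate: int = 2000
    mode_shift: float = 0.08  # h^-1
    slow_up: float = 20.0  # percentage points added to the slow weight
    slow_down: float = 8.0  # percentage points removed from the slow weight
    wt_replicates: int = 16
    # day-to-day replicate variation: each replicate's component means shift
    # together by N(0, mean_jitter_sd) and its slow weight wobbles by
    # N(0, slow_weight_jitter_sd) — kept small enough that replicates stay
    # reproducible under the K-S / mean-shift admissibility rules
    mean_jitter_sd: float = 0.007  # h^-1
    slow_weight_jitter_sd: float = 0.005
    rng_seed: int = 0
    category_assignments: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.category_assignments is not None:
            bad = set(self.category_assignments.values()) - set(CATEGORIES)
            if bad:
                raise ValueError(f"unknown categories: {sorted(bad)}")

    def assignments(self) -> dict[str, str]:
        if self.category_assignments is not None:
            return dict(self.category_assignments)
        return {f"strain{i:03d}": CATEGORIES[i % len(CATEGORIES)]
                for i in range(self.n_strains)}


# --------------------------------------------------------------------------
# Time-lapse rendering


@dataclass
class TimelapseResult:
    stack: np.ndarray  # (n_frames, H, W) uint16
    ground_truth: pd.DataFrame  # colony_id, frame, time_h, area_px, centroid, flags
    contacts: pd.DataFrame  # colony_a, colony_b, frame of first contact
    frame_interval_h: float = 1.5

    def first_contact(self, colony_id: int) -> int | None:
        sel = self.contacts[(self.contacts["colony_a"] == colony_id)
                            | (self.contacts["colony_b"] == colony_id)]
        return int(sel["frame"].min()) if len(sel) else None


def _sorted_disc_offsets(max_area: int) -> np.ndarray:
    """All (dr, dc) offsets within the radius covering max_area pixels,
    sorted by distance from the origin (ties by dr then dc).  Taking the
    first N offsets yields a pixel-exact, nested sequence of discs."""
    r = int(math.ceil(math.sqrt(max_area / math.pi))) + 3
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dr ** 2 + dc ** 2
    flat = np.stack([d2.ravel(), dr.ravel(), dc.ravel()], axis=1)
    order = np.lexsort((flat[:, 2], flat[:, 1], flat[:, 0]))
    out = flat[order][:, 1:]
    if len(out) < max_area:
        raise AssertionError("offset table smaller than requested area")
    return out.astype(np.int64)


def generate_timelapse(
    colony_specs: list[ColonySpec],
    frame_interval: float = 1.5,
    n_frames: int = 9,
    image_shape: tuple[int, int] = (512, 512),
    noise_sd: float = 1.0,
    rng_seed: int = 0,
) -> TimelapseResult:
    """Render a seeded grayscale time-lapse of growing microcolonies.

    Each colony is a disc of alternating bright/dark texture whose pixel
    area follows its spec's exponential law exactly; the background is
    Gaussian noise around a mid intensity.  The ground-truth table carries
    the true per-frame area and centroid; colonies whose disc would leave
    the frame are marked ``truncated`` and first contacts between colonies
    are recorded.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    ids = [c.colony_id for c in colony_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("colony_ids must be unique")
    rng = np.random.default_rng(rng_seed)
    H, W = image_shape
    max_area = max(c.area_at((n_frames - 1) * frame_interval) for c in colony_specs)
    offsets = _sorted_disc_offsets(max_area + 8)

    # t=0 overlap / fit check
    canvas0 = np.zeros((H, W), dtype=np.int32)
    for c in colony_specs:
        n0 = c.area_at(0.0)
        rr = c.seed_position[0] + offsets[:n0, 0]
        cc = c.seed_position[1] + offsets[:n0, 1]
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= H or cc.max() >= W:
            raise ValueError(f"colony {c.colony_id} does not fit in frame at t=0")
        if np.any(canvas0[rr, cc] != 0):
            raise ValueError(f"colony {c.colony_id} overlaps another colony at t=0")
        canvas0[rr, cc] = c.colony_id + 1

    checker_sign = {c.colony_id: 1 if (c.texture_seed % 2 == 0) else -1
                    for c in colony_specs}
    stack = np.empty((n_frames, H, W), dtype=np.uint16)
    gt_rows: list[dict] = []
    contact_first: dict[tuple[int, int], int] = {}
    truncated_ids: set[int] = set()

    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for f in range(n_frames):
        t = f * frame_interval
        frame = rng.normal(BACKGROUND_MEAN, noise_sd, size=(H, W))
        canvas = np.zeros((H, W), dtype=np.int32)
        for c in colony_specs:
            n = c.area_at(t)
            rr = c.seed_position[0] + offsets[:n, 0]
            cc = c.seed_position[1] + offsets[:n, 1]
            inside = (rr >= 0) & (cc >= 0) & (rr < H) & (cc < W)
            if not inside.all():
                truncated_ids.add(c.colony_id)
                rr, cc = rr[inside], cc[inside]
            # contact check against colonies already painted this frame,
            # including 8-adjacency
            neighbors: set[int] = set(np.unique(canvas[rr, cc]).tolist())
            for dr, dc in shifts:
                r2 = np.clip(rr + dr, 0, H - 1)
                c2 = np.clip(cc + dc, 0, W - 1)
                neighbors.update(np.unique(canvas[r2, c2]).tolist())
            neighbors.discard(0)
            for other in neighbors:
                pair = tuple(sorted((other - 1, c.colony_id)))
                contact_first.setdefault(pair, f)
            canvas[rr, cc] = c.colony_id + 1
            checker = ((rr + cc) % 2) * 2 - 1
            frame[rr, cc] = BACKGROUND_MEAN + checker_sign[c.colony_id] \
                * TEXTURE_AMPLITUDE * checker
            gt_rows.append({
                "colony_id": c.colony_id, "frame": f, "time_h": t,
                "area_px": c.area_at(t),
                "centroid_row": c.seed_position[0],
                "centroid_col": c.seed_position[1],
                "truncated": c.colony_id in truncated_ids,
            })
        stack[f] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)

    contacts = pd.DataFrame(
        [{"colony_a": a, "colony_b": b, "frame": f}
         for (a, b), f in sorted(contact_first.items())],
        columns=["colony_a", "colony_b", "frame"],
    )
    gt = pd.DataFrame(gt_rows)
    touched = {cid: f for (a, b), f in contact_first.items() for cid in (a, b)}
    gt["touched"] = [
        touched.get(cid, np.inf) <= fr
        for cid, fr in zip(gt["colony_id"], gt["frame"])
    ]
    return TimelapseResult(stack=stack, ground_truth=gt, contacts=contacts,
                           frame_interval_h=frame_interval)


def grid_colony_specs(
    n_colonies: int,
    image_shape: tuple[int, int],
    rates: np.ndarray | float,
    initial_area: int = 100,
    margin: int = 90,
    jitter: int = 6,
    rng_seed: int = 0,
    lag_durations: np.ndarray | float = 0.0,
    id_offset: int = 0,
) -> list[ColonySpec]:
    """Lay colonies on a jittered grid with enough pitch to avoid collisions
    over the observation window (for the default 12 h at ~0.4 h^-1)."""
    rng = np.random.default_rng(rng_seed)
    H, W = image_shape
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (n_colonies,))
    lags = np.broadcast_to(np.asarray(lag_durations, dtype=float), (n_colonies,))
    ncols = max(1, int(math.ceil(math.sqrt(n_colonies * W / H))))
    nrows = int(math.ceil(n_colonies / ncols))
    pitch_r = (H - 2 * margin) / nrows
    pitch_c = (W - 2 * margin) / ncols
    # margin doubles as the per-colony safety radius: neighbouring centres
    # must stay >= 2*margin apart (minus jitter) to rule out collisions
    if min(pitch_r, pitch_c) < 2 * margin - 2 * jitter:
        raise ValueError("too many colonies for the frame at this margin")
    specs = []
    for i in range(n_colonies):
        r = margin + (i // ncols + 0.5) * pitch_r + rng.integers(-jitter, jitter + 1)
        c = margin + (i % ncols + 0.5) * pitch_c + rng.integers(-jitter, jitter + 1)
        specs.append(ColonySpec(
            colony_id=id_offset + i,
            seed_position=(int(r), int(c)),
            initial_area=initial_area,
            true_rate=float(rates[i]),
            lag_duration=float(lags[i]),
            texture_seed=int(rng.integers(0, 2 ** 16)),
        ))
    return specs


def save_timelapse(result: TimelapseResult, outdir: str | Path) -> Path:
    """Write the stack as zero-padded 16-bit TIFF frames plus a JSON
    ground-truth sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for f in range(result.stack.shape[0]):
        tifffile.imwrite(outdir / f"frame_{f:03d}.tif", result.stack[f])
    sidecar = {
        "frame_interval_h": result.frame_interval_h,
        "ground_truth": result.ground_truth.to_dict(orient="records"),
        "contacts": result.contacts.to_dict(orient="records"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar))
    return outdir


def load_timelapse(indir: str | Path) -> TimelapseResult:
    import tifffile

    indir = Path(indir)
    paths = sorted(indir.glob("frame_*.tif"),
                   key=lambda p: int(re.search(r"(\d+)", p.stem).group(1)))
    if not paths:
        raise FileNotFoundError(f"no frame_*.tif files in {indir}")
    stack = np.stack([tifffile.imread(p) for p in paths])
    sidecar_path = indir / "ground_truth.json"
    interval, gt, contacts = 1.5, pd.DataFrame(), pd.DataFrame()
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        interval = sidecar.get("frame_interval_h", 1.5)
        gt = pd.DataFrame(sidecar.get("ground_truth", []))
        contacts = pd.DataFrame(sidecar.get("contacts", []),
                                columns=["colony_a", "colony_b", "frame"])
    return TimelapseResult(stack=stack, ground_truth=gt, contacts=contacts,
                           frame_interval_h=interval)


# --------------------------------------------------------------------------
# Growth-rate mixtures and planted screens


def generate_rate_mixture(spec: MixtureSpec) -> pd.DataFrame:
    """Draw growth rates from a truncated-normal mixture.

    Returns a frame (rate, component) where ``component`` indexes the
    originating mixture component (ground-truth label).
    """
    rng = np.random.default_rng(spec.rng_seed)
    weights = np.array([c[0] for c in spec.components])
    labels = rng.choice(len(spec.components), size=spec.n_colonies, p=weights)
    rates = np.empty(spec.n_colonies)
    for i, (_, mean, sd) in enumerate(spec.components):
        idx = np.flatnonzero(labels == i)
        draws = rng.normal(mean, sd, size=idx.size)
        bad = np.flatnonzero(draws < 0)
        while bad.size:  # truncate at 0 by redrawing
            draws[bad] = rng.normal(mean, sd, size=bad.size)
            bad = bad[draws[bad] < 0]
        rates[idx] = draws
    return pd.DataFrame({"rate": rates, "component": labels})


def _modified_mixture(category: str, spec: PlantedScreenSpec) -> tuple:
    (w_fast, m_fast, s_fast), (w_slow, m_slow, s_slow) = WT_MIXTURE
    up = min(0.95 - w_slow, spec.slow_up / 100.0)
    down = min(w_slow - 0.005, spec.slow_down / 100.0)
    shift = spec.mode_shift
    if category == "no-change":
        pass
    elif category == "mode-only":
        m_fast -= shift
    elif category == "slow-down-only":
        w_slow -= down
    elif category == "slow-up-only":
        w_slow += up
    elif category == "both-down":
        m_fast -= shift
        w_slow -= down
    elif category == "mode-down-slow-up":
        m_fast -= shift
        w_slow += up
    elif category == "other":  # mode up with a larger slow fraction
        m_fast += shift
        w_slow += up
    else:
        raise ValueError(f"unknown category {category!r}")
    w_fast = 1.0 - w_slow
    return ((w_fast, m_fast, s_fast), (w_slow, m_slow, s_slow))


def generate_screen(spec: PlantedScreenSpec) -> dict:
    """Build a planted deletion screen.

    Returns ``{"wt": [rate arrays], "strains": {strain: {"category": str,
    "replicates": [rate arrays]}}}`` with one rate vector per replicate.
    """
    root = np.random.default_rng(spec.rng_seed)
    max_seed = 2 ** 31 - 1

    def draws(components, n):
        # day-to-day replicate variation: common mean shift + slow-weight wobble
        shift = root.normal(0.0, spec.mean_jitter_sd)
        wobble = root.normal(0.0, spec.slow_weight_jitter_sd)
        (w_f, m_f, s_f), (w_s, m_s, s_s) = components
        w_s = float(np.clip(w_s + wobble, 0.005, 0.95))
        jittered = ((1.0 - w_s, max(m_f + shift, 0.01), s_f),
                    (w_s, max(m_s + shift, 0.01), s_s))
        sub = MixtureSpec(components=jittered, n_colonies=n,
                          rng_seed=int(root.integers(max_seed)))
        return generate_rate_mixture(sub)["rate"].to_numpy()

    wt = [draws(WT_MIXTURE, spec.n_per_replicate) for _ in range(spec.wt_replicates)]
    strains = {}
    for strain, category in spec.assignments().items():
        comps = _modified_mixture(category, spec)
        strains[strain] = {
            "category": category,
            "replicates": [draws(comps, spec.n_per_replicate)
                           for _ in range(spec.replicates)],
        }
    return {"wt": wt, "strains": strains}


# --------------------------------------------------------------------------
# Branching state-switching population


@dataclass
class SwitchingPopulation:
    """Outcome of the agent-based branching simulation.

    ``counts`` holds (founder_state, state, n, weight) at the horizon;
    ``history`` the per-step state totals.  ``weight`` > 1 records the
    subsampling factor applied when the population exceeded the cap.
    """

    counts: pd.DataFrame
    history: pd.DataFrame

    @property
    def total(self) -> float:
        return float((self.counts["n"] * self.counts["weight"]).sum())

    def state_fraction(self, state: str) -> float:
        sel = self.counts["state"] == state
        return float((self.counts.loc[sel, "n"] * self.counts.loc[sel, "weight"]).sum()
                     / self.total)

    def to_cells(self, max_cells: int = 100_000, rng_seed: int = 0) -> pd.DataFrame:
        """Expand to a per-cell table (cell_id, founder_state, state, weight),
        subsampling uniformly if the population exceeds ``max_cells``."""
        rows = self.counts.loc[self.counts["n"] > 0]
        reps = rows["n"].to_numpy()
        founder = np.repeat(rows["founder_state"].to_numpy(), reps)
        state = np.repeat(rows["state"].to_numpy(), reps)
        weight = np.repeat(rows["weight"].to_numpy(), reps)
        n = founder.size
        if n > max_cells:
            rng = np.random.default_rng(rng_seed)
            idx = rng.choice(n, size=max_cells, replace=False)
            founder, state = founder[idx], state[idx]
            weight = weight[idx] * (n / max_cells)
        return pd.DataFrame({"cell_id": np.arange(founder.size),
                             "founder_state": founder, "state": state,
                             "weight": weight})


def per_step_probability(p_per_24h: float, dt_h: float) -> float:
    """Convert a per-24 h switching fraction to a per-step probability via
    the exponential hazard: p_dt = 1 - (1 - p24)^(dt/24)."""
    if not 0.0 <= p_per_24h <= 1.0:
        raise ValueError("per-24 h probability must be in [0, 1]")
    return 1.0 - (1.0 - p_per_24h) ** (dt_h / 24.0)


def generate_switching_population(
    params: SwitchingModelParams,
    horizon: float = 24.0,
    dt: float = 0.5,
    rng_seed: int = 0,
    n_initial: int = 2000,
    switch_high_to_low_per24: float = 0.0,
    cap: int = 5_000_000,
) -> SwitchingPopulation:
    """Forward-simulate the branching three-state population.

    States: "slow" and "fast" (high membrane potential) and "low".  Each
    step every cell divides with the Yule-process offspring law for its
    state's growth rate (one cell leaves a Geometric(e^(-r*dt)) number of
    descendants, so expected growth is exactly e^(r*t)), then low cells
    switch to the fast-high state with the per-step hazard converted from
    ``params.s_low_to_high`` (and optionally high cells switch to low).
    """
    n_steps_f = horizon / dt
    if abs(n_steps_f - round(n_steps_f)) > 1e-9:
        raise ValueError("dt must divide horizon")
    n_steps = int(round(n_steps_f))
    rng = np.random.default_rng(rng_seed)
    rates = {"slow": params.r_slow, "fast": params.r_fast, "low": params.r_fast}
    p_div = {s: 1.0 - math.exp(-r * dt) for s, r in rates.items()}
    p_lh = per_step_probability(params.s_low_to_high, dt)
    p_hl = per_step_probability(switch_high_to_low_per24, dt)

    init = {"slow": params.f_slow, "fast": params.f_fast, "low": params.f_low0}
    counts = {(s, s): int(round(n_initial * f)) for s, f in init.items()}
    weight = 1.0
    hist_rows = []

    def totals():
        out = {"slow": 0, "fast": 0, "low": 0}
        for (_, s), n in counts.items():
            out[s] += n
        return out

    for step in range(n_steps):
        hist_rows.append({"time_h": step * dt, **totals(), "weight": weight})
        new: dict[tuple[str, str], int] = {}
        for (founder, state), n in counts.items():
            if n == 0:
                continue
            # Yule offspring: n survivors + NB(n, e^(-r dt)) extra descendants
            p_keep = 1.0 - p_div[state]
            n_grown = n + int(rng.negative_binomial(n, p_keep)) if p_keep < 1.0 else n
            if state == "low" and p_lh > 0:
                k = int(rng.binomial(n_grown, p_lh))
                new[(founder, "fast")] = new.get((founder, "fast"), 0) + k
                n_grown -= k
            elif state in ("slow", "fast") and p_hl > 0:
                k = int(rng.binomial(n_grown, p_hl))
                new[(founder, "low")] = new.get((founder, "low"), 0) + k
                n_grown -= k
            new[(founder, state)] = new.get((founder, state), 0) + n_grown
        total = sum(new.values())
        if total > cap:
            f = cap / total
            new = {k: int(rng.binomial(n, f)) for k, n in new.items()}
            weight /= f
        counts = new
    hist_rows.append({"time_h": n_steps * dt, **totals(), "weight": weight})

    count_df = pd.DataFrame(
        [{"founder_state": f0, "state": s, "n": n, "weight": weight}
         for (f0, s), n in sorted(counts.items())],
        columns=["founder_state", "state", "n", "weight"],
    )
    return SwitchingPopulation(counts=count_df, history=pd.DataFrame(hist_rows))


# --------------------------------------------------------------------------
# Annotation tables and qPCR plates


def generate_annotation(
    n_genes: int,
    n_terms: int,
    planted: tuple[str, int, float] | None = None,
    rng_seed: int = 0,
    base_frequency: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Fabricate a flat gene-to-term annotation table.

    ``planted`` = (term, group_size, fold) makes one term over-represented
    in the first ``group_size`` genes by the stated fold relative to
    ``base_frequency``.  Returns (annotation frame with columns gene/term,
    group gene list).
    """
    rng = np.random.default_rng(rng_seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    terms = [f"term{i:02d}" for i in range(n_terms)]
    group: list[str] = []
    rows = []
    planted_term, fold = None, 1.0
    if planted is not None:
        planted_term, group_size, fold = planted
        if fold < 1:
            raise ValueError("enrichment fold must be >= 1")
        if fold * base_frequency > 1:
            raise ValueError(
                f"fold {fold} infeasible: in-group frequency would exceed 1")
        if planted_term not in terms:
            terms.append(str(planted_term))
        group = genes[:group_size]
    group_set = set(group)
    freqs = {t: base_frequency for t in terms}
    for g in genes:
        for t in terms:
            p = freqs[t]
            if t == planted_term and g in group_set:
                p = fold * base_frequency
            if rng.random() < p:
                rows.append({"gene": g, "term": t})
    return pd.DataFrame(rows, columns=["gene", "term"]), group


def generate_qpcr_plate(
    true_copy_ratio: float,
    n_mt_primers: int = 5,
    n_nuc_primers: int = 5,
    n_tech_reps: int = 3,
    dilution_fold: float = 4.0,
    n_dilutions: int = 6,
    efficiency: float = 1.0,
    ct_noise_sd: float = 0.0,
    rng_seed: int = 0,
    label: str = "sample",
) -> QpcrPlate:
    """Fabricate a qPCR plate: per-primer standard curves from a serial
    dilution series plus technical-replicate sample reactions.

    Ct follows the standard amplification model
    ``Ct = intercept + slope * log10(quantity)`` with
    ``slope = -1/log10(1 + efficiency)`` (−3.32 at 100% efficiency); the
    nuclear sample quantity is 1 and the mitochondrial quantity is the true
    copy ratio.  Defaults mirror a 5+5 primer × 3 replicate layout (30
    sample reactions) with six 4-fold dilutions.
    """
    if not 0.7 < efficiency <= 1.1:
        raise ValueError("efficiency must be in (0.7, 1.1]")
    rng = np.random.default_rng(rng_seed)
    slope = -1.0 / math.log10(1.0 + efficiency)
    primers = ([(f"mt{i:02d}", "mt", float(true_copy_ratio))
                for i in range(n_mt_primers)]
               + [(f"nuc{i:02d}", "nuclear", 1.0) for i in range(n_nuc_primers)])
    top_quantity = 50.0
    std_quantities = top_quantity / dilution_fold ** np.arange(n_dilutions)
    rows = []
    for name, target, sample_q in primers:
        intercept = float(rng.uniform(20.0, 26.0))
        for q in std_quantities:
            ct = intercept + slope * math.log10(q) + rng.normal(0.0, ct_noise_sd)
            rows.append({"primer": name, "target": target, "role": "standard",
                         "quantity": float(q), "ct": float(ct)})
        for _ in range(n_tech_reps):
            ct = intercept + slope * math.log10(sample_q) \
                + rng.normal(0.0, ct_noise_sd)
            rows.append({"primer": name, "target": target, "role": "sample",
                         "quantity": float("nan"), "ct": float(ct)})
    return QpcrPlate(data=pd.DataFrame(rows), label=label)
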