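"""Recursive electrogram-guided localization of re-entrant drivers.

Starting from a random probe position, the algorithm records a 3x3
multiprobe, extracts features, and asks the forests two questions:
"am I on the driver's x/y band?" (stop test) and "where is the driver?"
(displacement distributions).  Each prediction is clipped to a running
constraint region; the sign of the constrained prediction relative to
the current probe marks the half-space (x) / half-circle arc (y)
containing the driver, and the region is intersected with it before the
probe jumps to the predicted position.  A prediction error is declared
when the region collapses below one probe footprint or a position is
revisited.  The multi-driver extension checks the row where wavefronts
from a found driver should collide; through-traffic there reveals a
second driver on the side the waves come from, and the search repeats
inside that arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice_model as lm
from .electrogram import (
    DEFAULT_DURATION,
    PROBE_SPACING,
    ElectrogramEngine,
    FibrillationWindow,
    make_multiprobe,
)
from .features import activation_times, feature_vector
from .forest_models import (
    ModelBundle,
    bin_midpoint,
    class_probabilities,
    probe_on_circuit,
)

MIN_REGION_WIDTH = 7  # one probe footprint; below this the region has collapsed
DEFAULT_JUMP_LIMIT = 30
# A half-space cut is only applied when the constrained displacement
# distribution puts at least this fraction of its mass strictly on one
# side of the probe; the sign of a marginal prediction is noise and a
# wrong cut permanently excludes the driver.
SIDE_MASS_THRESHOLD = 0.75
# A positive is accepted outright only once the row locator also points
# at the current probe (within its own on-band accuracy of ~2 rows);
# otherwise the positive is kept as a candidate and the walk continues,
# accepting when it loops back to within this radius of a previous
# positive.  This is the confirm-and-refine reading of the final step:
# a recording at the predicted position must remain consistent with
# sitting on a driver before the search ends.
STOP_SETTLE_Y = 2.0
LOOP_ACCEPT_RADIUS = 2


def _row_arc_mask(L: int, start: int, length: int) -> np.ndarray:
    """Boolean mask of the arc [start, start+length) on the row circle."""
    mask = np.zeros(L, dtype=bool)
    idx = (start + np.arange(length)) % L
    mask[idx] = True
    return mask


def _largest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the largest contiguous circular run of True."""
    L = mask.size
    if mask.all():
        return 0, L
    if not mask.any():
        return 0, 0
    # rotate so index 0 is False, then runs do not wrap
    first_false = int(np.argmax(~mask))
    rolled = np.roll(mask, -first_false)
    best_start, best_len = 0, 0
    i = 0
    while i < L:
        if rolled[i]:
            j = i
            while j < L and rolled[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    return (best_start + first_false) % L, best_len


@dataclass
class ConstraintRegion:
    """Admissible driver locations: a column interval (open boundaries)
    crossed with an arc mask on the periodic row circle."""

    x_lo: int
    x_hi: int
    y_mask: np.ndarray
    provenance: list = field(default_factory=list)

    @classmethod
    def full(cls, L: int) -> "ConstraintRegion":
        return cls(x_lo=0, x_hi=L - 1, y_mask=np.ones(L, dtype=bool))

    @property
    def L(self) -> int:
        return self.y_mask.size

    @property
    def x_width(self) -> int:
        return max(0, self.x_hi - self.x_lo + 1)

    @property
    def y_width(self) -> int:
        return int(self.y_mask.sum())

    def contains(self, row: int, col: int) -> bool:
        return self.x_lo <= col <= self.x_hi and bool(self.y_mask[row % self.L])

    def x_midpoint(self) -> int:
        return (self.x_lo + self.x_hi) // 2

    def y_midpoint(self) -> int:
        start, length = _largest_run(self.y_mask)
        return (start + length // 2) % self.L

    def copy(self) -> "ConstraintRegion":
        return ConstraintRegion(
            self.x_lo, self.x_hi, self.y_mask.copy(), list(self.provenance)
        )


@dataclass
class SearchState:
    centre: tuple[int, int]
    region: ConstraintRegion
    visited: list[tuple[int, int]] = field(default_factory=list)

    @property
    def jumps(self) -> int:
        return len(self.visited)


@dataclass
class SearchResult:
    centre: tuple[int, int]
    positive: bool
    success: bool
    jumps: int
    failure_mode: str | None  # None | "prediction_error" | "jump_limit" | "no_driver_expected"
    visited: list[tuple[int, int]] = field(default_factory=list)


def _clamp_probe_col(col: int, L: int) -> int:
    return int(np.clip(col, 3, L - 4))


def init_search(
    tissue: lm.Tissue,
    rng: np.random.Generator,
    region: ConstraintRegion | None = None,
) -> SearchState:
    """Random initial probe centre inside the (given or full) region."""
    L = tissue.L
    region = region.copy() if region is not None else ConstraintRegion.full(L)
    rows = np.nonzero(region.y_mask)[0]
    row = int(rng.choice(rows))
    lo = max(region.x_lo, 3)
    hi = min(region.x_hi, L - 4)
    if lo > hi:
        lo, hi = 3, L - 4
    col = int(rng.integers(lo, hi + 1))
    return SearchState(centre=(row, col), region=region)


@dataclass
class AxisDistribution:
    """One locator's constrained view from the current probe: absolute
    coordinates per displacement bin, vote probabilities, and the
    in-region validity mask."""

    coords: np.ndarray
    probs: np.ndarray
    in_region: np.ndarray

    def side_masses(self, probe_coord: int, wrap: int | None) -> tuple[float, float]:
        """(mass strictly ahead of the probe, mass strictly behind),
        renormalized over the in-region bins."""
        total = self.probs[self.in_region].sum()
        if total <= 0:
            return 0.0, 0.0
        if wrap is None:
            delta = self.coords - probe_coord
        else:
            delta = (self.coords - probe_coord + wrap / 2) % wrap - wrap / 2
        pos = self.probs[self.in_region & (delta > 0)].sum() / total
        neg = self.probs[self.in_region & (delta < 0)].sum() / total
        return float(pos), float(neg)


def axis_distributions(
    bundle: ModelBundle,
    features: np.ndarray,
    state: SearchState,
) -> dict[str, AxisDistribution]:
    """Constrained displacement distributions for both axes."""
    region = state.region
    L = region.L
    row0, col0 = state.centre
    labels_x, probs_x = class_probabilities(bundle.prob_x, features)
    coords_x = (col0 + bin_midpoint(labels_x, bundle.bin_width_x)).astype(int)
    in_x = (coords_x >= region.x_lo) & (coords_x <= region.x_hi)
    labels_y, probs_y = class_probabilities(bundle.prob_y, features)
    coords_y = ((row0 + bin_midpoint(labels_y, bundle.bin_width_y)) % L).astype(int)
    in_y = region.y_mask[coords_y]
    return {
        "x": AxisDistribution(coords_x, probs_x, in_x),
        "y": AxisDistribution(coords_y, probs_y, in_y),
    }


def _constrained_axis_prediction(
    dist: AxisDistribution,
    midpoint: int,
    wrap: int | None,
) -> int:
    """Pick the argmax displacement bin whose absolute coordinate lies in
    the region; ties go to the bin nearest the region midpoint, then to
    the smaller coordinate.  Falls back to the region midpoint when no
    mass lies inside."""
    ok = dist.in_region
    if not ok.any() or dist.probs[ok].sum() <= 0:
        return int(midpoint)
    p = np.where(ok, dist.probs, -1.0)
    best = p.max()
    cand = np.nonzero(p >= best - 1e-12)[0]
    coords = dist.coords
    if wrap is not None:
        d = np.abs((coords[cand] - midpoint + wrap / 2) % wrap - wrap / 2)
    else:
        d = np.abs(coords[cand] - midpoint)
    order = np.lexsort((coords[cand], d))
    return int(coords[cand[order[0]]])


def propose_position(
    bundle: ModelBundle,
    features: np.ndarray,
    state: SearchState,
    dists: dict[str, AxisDistribution] | None = None,
) -> tuple[int, int]:
    """Next probe centre from the constrained displacement distributions.

    Centres that were already visited (and judged negative there) are
    excluded by falling back to the next-best joint bin; when every
    candidate is visited the best one is returned and the revisit is
    left for update_constraints to flag.
    """
    region = state.region
    L = region.L
    if dists is None:
        dists = axis_distributions(bundle, features, state)
    col = _constrained_axis_prediction(dists["x"], region.x_midpoint(), wrap=None)
    row = _constrained_axis_prediction(dists["y"], region.y_midpoint(), wrap=L)
    best = (int(row) % L, int(col))
    if (best[0], _clamp_probe_col(best[1], L)) not in state.visited:
        return best
    # joint next-best: rank in-region (row, col) bin pairs by vote mass
    dx, dy = dists["x"], dists["y"]
    ok_x = np.nonzero(dx.in_region)[0]
    ok_y = np.nonzero(dy.in_region)[0]
    if ok_x.size and ok_y.size:
        joint = dx.probs[ok_x][:, None] * dy.probs[ok_y][None, :]
        order = np.argsort(joint.ravel())[::-1]
        for flat in order[:200]:
            i, j = ok_x[flat // ok_y.size], ok_y[flat % ok_y.size]
            cand = (int(dy.coords[j]) % L, int(dx.coords[i]))
            if joint.ravel()[flat] <= 0:
                break
            if (cand[0], _clamp_probe_col(cand[1], L)) not in state.visited:
                return cand
    return best


def update_constraints(
    state: SearchState,
    proposal: tuple[int, int],
    dists: dict[str, AxisDistribution] | None = None,
) -> tuple[ConstraintRegion, str | None]:
    """Intersect the region with the half-spaces the locators point into.

    Per axis, the side of the current probe holding the driver is
    inferred from the constrained displacement distribution; the cut is
    only applied when at least SIDE_MASS_THRESHOLD of the in-region
    mass lies strictly on one side (without distributions, the sign of
    the proposal's displacement decides, unconditionally).

    Returns (region, error): error is "prediction_error" when the
    region drops below one probe footprint on either axis or the
    proposal revisits a previous centre.
    """
    region = state.region.copy()
    L = region.L
    row0, col0 = state.centre
    prow, pcol = proposal

    if dists is not None:
        pos, neg = dists["x"].side_masses(col0, wrap=None)
        sx = 1 if pos >= SIDE_MASS_THRESHOLD else (-1 if neg >= SIDE_MASS_THRESHOLD else 0)
    else:
        sx = int(np.sign(pcol - col0))
    if sx > 0:
        region.x_lo = max(region.x_lo, col0 + 1)
    elif sx < 0:
        region.x_hi = min(region.x_hi, col0 - 1)

    if dists is not None:
        pos, neg = dists["y"].side_masses(row0, wrap=L)
        sy = 1 if pos >= SIDE_MASS_THRESHOLD else (-1 if neg >= SIDE_MASS_THRESHOLD else 0)
    else:
        dy = (prow - row0 + L / 2) % L - L / 2
        sy = 1 if dy > 0 else (-1 if dy < 0 else 0)
    if sy > 0:
        region.y_mask &= _row_arc_mask(L, row0 + 1, L // 2)
    elif sy < 0:
        region.y_mask &= _row_arc_mask(L, row0 - L // 2, L // 2)
    region.provenance.append((state.centre, sx, sy))

    error = None
    # a thin interval flush against an open boundary is still a valid
    # target (one probe placement covers it), so only interior x-slivers
    # count as collapse
    x_collapsed = (
        region.x_width < MIN_REGION_WIDTH
        and region.x_lo > 0
        and region.x_hi < L - 1
    )
    if x_collapsed or region.y_width < MIN_REGION_WIDTH:
        error = "prediction_error"
    clamped = (prow % L, _clamp_probe_col(pcol, L))
    if clamped in state.visited:
        error = "prediction_error"
    return region, error


def _axis_move(dist: AxisDistribution, coord0: int, wrap: int | None) -> float:
    """Displacement of the best in-region bin from the current coordinate."""
    ok = dist.in_region
    if not ok.any() or dist.probs[ok].sum() <= 0:
        return 0.0
    coord = int(dist.coords[int(np.argmax(np.where(ok, dist.probs, -1.0)))])
    if wrap is None:
        return float(coord - coord0)
    return float((coord - coord0 + wrap / 2) % wrap - wrap / 2)


def check_positive(bundle: ModelBundle, features: np.ndarray) -> bool:
    """True when both on-axis classifiers fire: their conjunction
    approximates 'the probe is on the circuit'."""
    on_x, on_y = bundle.on_axis(features)
    return on_x and on_y


def _success(centre: tuple[int, int], circuits, L: int) -> bool:
    return any(probe_on_circuit(centre, c, L) for c in circuits)


def locate_driver(
    sim: lm.Simulation,
    bundle: ModelBundle,
    rng: np.random.Generator,
    circuits: list[lm.CircuitSpec] | None = None,
    jump_limit: int = DEFAULT_JUMP_LIMIT,
    region: ConstraintRegion | None = None,
    duration: int = DEFAULT_DURATION,
    window: FibrillationWindow | None = None,
) -> SearchResult:
    """Run the record -> classify -> propose -> constrain -> move loop.

    All jumps read from one captured fibrillatory window (the driver is
    stationary, so every probe sees the same episode, exactly as the
    training probes do).  Ends with a positive when both on-axis
    classifiers fire at the current probe; each multiprobe recording
    counts as one jump.  Success is judged against the ground-truth
    circuit footprints when they are provided.
    """
    tissue = sim.tissue
    L = tissue.L
    if window is None:
        window = FibrillationWindow.capture(sim, duration)
    state = init_search(tissue, rng, region)
    circuits = circuits or []
    positive_centres: list[tuple[int, int]] = []

    def _result(centre, positive, mode):
        return SearchResult(
            centre=centre,
            positive=positive,
            success=(_success(centre, circuits, L) if circuits else positive),
            jumps=state.jumps,
            failure_mode=mode,
            visited=list(state.visited),
        )

    def _fallback(mode):
        # the walk ran out of road; if it passed any positives, the most
        # recent one stands as the final prediction
        if positive_centres:
            return _result(positive_centres[-1], True, None)
        return _result(state.centre, False, mode)

    if jump_limit <= 0:
        return SearchResult(
            centre=state.centre, positive=False,
            success=False, jumps=0, failure_mode="jump_limit", visited=[],
        )
    while True:
        probe = make_multiprobe(state.centre, L)
        rec = window.record(probe)
        state.visited.append(state.centre)
        fv = feature_vector(rec)
        dists = axis_distributions(bundle, fv, state)

        if check_positive(bundle, fv):
            settled = abs(_axis_move(dists["y"], state.centre[0], L)) <= STOP_SETTLE_Y
            looped = any(
                max(
                    abs((state.centre[0] - p[0] + L / 2) % L - L / 2),
                    abs(state.centre[1] - p[1]),
                )
                <= LOOP_ACCEPT_RADIUS
                for p in positive_centres
            )
            if settled or looped:
                return _result(state.centre, True, None)
            positive_centres.append(state.centre)
        if state.jumps >= jump_limit:
            return _fallback("jump_limit")
        proposal = propose_position(bundle, fv, state, dists=dists)
        new_region, error = update_constraints(state, proposal, dists=dists)
        if error is not None:
            return _fallback(error)
        state.region = new_region
        state.centre = (proposal[0] % L, _clamp_probe_col(proposal[1], L))


def expected_collision_rows(found_rows: list[int], L: int) -> list[int]:
    """Rows where wavefronts from the found driver(s) should collide.

    One driver on the periodic row circle -> its antipode; two drivers
    -> the two mid-rows of the arcs between them (equal wave speeds)."""
    if not found_rows:
        raise ValueError("at least one found driver row is required")
    if len(found_rows) == 1:
        return [(found_rows[0] + L // 2) % L]
    a, b = sorted(r % L for r in found_rows[:2])
    return [((a + b) // 2) % L, ((a + b + L) // 2) % L]


# Through-traffic at nu=0.2 advances ~0.2 cells/step transversely, a
# slope of ~5 steps/cell; a symmetric collision has slope ~0.  The
# decision threshold sits well below the through-traffic slope.
COLLISION_SLOPE_THRESHOLD = 1.5  # steps per cell


def classify_collision(
    voltages: np.ndarray, period: int = 60
) -> tuple[bool, int]:
    """Collision vs through-traffic at a probe from activation times.

    The mean activation-time slope along y across the probe decides:
    near zero means wavefronts meet under the probe (collision), a
    clear slope means traffic passing through, moving towards +y
    (direction +1, times increase with y) or -y (-1).  Because
    activity is periodic, pairwise time differences are aliased into
    (-period/2, period/2] before averaging — electrodes can catch
    consecutive beats across the window boundary."""
    slope = collision_slope(voltages, period=period)
    if abs(slope) <= COLLISION_SLOPE_THRESHOLD:
        return True, 0
    return False, int(np.sign(slope))


def collision_slope(voltages: np.ndarray, period: int = 60) -> float:
    """Mean activation-time slope along y (steps/cell) across the probe,
    with pairwise differences aliased into (-period/2, period/2]."""
    times = activation_times(voltages).reshape(3, 3)
    diffs = (times[1:, :] - times[:-1, :]).ravel()
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size == 0:
        return 0.0
    diffs = (diffs + period / 2) % period - period / 2
    return float(np.mean(diffs)) / PROBE_SPACING


def locate_all(
    sim: lm.Simulation,
    bundle: ModelBundle,
    rng: np.random.Generator,
    circuits: list[lm.CircuitSpec] | None = None,
    n_expected: int = 2,
    jump_limit: int = DEFAULT_JUMP_LIMIT,
    duration: int = DEFAULT_DURATION,
    window: FibrillationWindow | None = None,
) -> list[SearchResult]:
    """Find up to ``n_expected`` drivers with the single-driver models.

    After the first driver is found, one multiprobe at its expected
    collision row decides whether a second driver exists: an observed
    collision ends the search; through-traffic constrains the second
    search to the arc the waves come from (excluding the found driver's
    rows) and the recursive search runs again inside it.
    """
    tissue = sim.tissue
    L = tissue.L
    circuits = circuits or []
    if window is None:
        window = FibrillationWindow.capture(sim, duration)

    first = locate_driver(
        sim, bundle, rng, circuits=circuits, jump_limit=jump_limit,
        duration=duration, window=window,
    )
    results = [first]
    if n_expected < 2 or not first.positive:
        return results

    # Find where wavefronts emanating from the found driver actually
    # collide.  A lone driver's waves meet at its antipodal row; a
    # displaced collision row betrays a second driver at the mirrored
    # position (equal wave speeds put the collision midway between the
    # sources).
    found_row, found_col = first.centre
    probe_col = _clamp_probe_col(found_col, L)
    extra_jumps = 0

    def slope_at(row: int) -> float:
        nonlocal extra_jumps
        extra_jumps += 1
        rec = window.record(make_multiprobe((row % L, probe_col), L))
        return collision_slope(rec.voltages)

    coll_row = _find_collision_row(found_row, slope_at, L)
    expected = expected_collision_rows([found_row], L)[0]
    displacement = abs((coll_row - expected + L / 2) % L - L / 2)

    region = ConstraintRegion.full(L)
    if displacement > COLLISION_TOLERANCE:
        # Second driver's row mirrors the first about the collision row.
        d2_row = int((2 * coll_row - found_row) % L)
        region.y_mask = _row_arc_mask(
            L,
            d2_row - SECOND_DRIVER_ARC_HALF_WIDTH,
            2 * SECOND_DRIVER_ARC_HALF_WIDTH + 1,
        )
    # A collision at the expected row is weak evidence against a second
    # driver: fast longitudinal sweeps often flatten the transverse
    # activation-time structure far from any driver.  The second search
    # therefore still runs, over the remaining rows, and reports no
    # driver only when it ends without a positive.
    region.y_mask &= ~_row_arc_mask(L, found_row - 8, 17)
    if region.y_width < MIN_REGION_WIDTH:
        region = ConstraintRegion.full(L)

    remaining = [c for c in circuits if not probe_on_circuit(first.centre, c, L)]
    second = locate_driver(
        sim, bundle, rng, circuits=remaining or circuits,
        jump_limit=jump_limit, region=region, duration=duration, window=window,
    )
    second.jumps += extra_jumps
    if not second.positive:
        second.failure_mode = second.failure_mode or "no_driver_expected"
    results.append(second)
    return results


# Collision-row localization: the y-slope of activation times flips
# sign across a collision row.  Rows closer than the tolerance to the
# lone-driver antipode are treated as the expected collision.
COLLISION_TOLERANCE = 6
SECOND_DRIVER_ARC_HALF_WIDTH = 25
_BISECT_STEPS = 5


def _find_collision_row(driver_row: int, slope_at, L: int) -> int:
    """Bisect for the row where the activation-time y-slope changes sign
    on the arc of rows driven by the found driver.

    slope_at(row) must return the (aliased) slope from a fresh probe
    recording at that row.  Waves leave the driver in both directions,
    so the slope is positive on the +y side, negative on the -y side,
    and crosses zero at the collision row.
    """
    m = (driver_row + L // 2) % L
    s_m = slope_at(m)
    if abs(s_m) <= COLLISION_SLOPE_THRESHOLD:
        # collision at or near the antipode: check symmetry a little
        # off-axis to catch a displaced collision sitting close to m
        off = 15
        s_lo, s_hi = slope_at((m - off) % L), slope_at((m + off) % L)
        if s_lo >= -COLLISION_SLOPE_THRESHOLD and s_hi <= COLLISION_SLOPE_THRESHOLD:
            return m  # +y traffic below, -y above: symmetric about m
        # asymmetric: the collision lies on the side showing the wrong
        # traffic direction
        if s_lo < 0:  # waves still moving -y below m: collision below
            return _bisect_sign_change(slope_at, m - L // 2 + 2, m - off, L)
        return _bisect_sign_change(slope_at, m + off, m + L // 2 - 2, L)
    if s_m > 0:  # traffic moving +y at m: collision above
        return _bisect_sign_change(slope_at, m, m + L // 2 - 2, L)
    return _bisect_sign_change(slope_at, m - L // 2 + 2, m, L)


def _bisect_sign_change(slope_at, lo: int, hi: int, L: int) -> int:
    """Row where the slope crosses zero on [lo, hi] (indices may exceed
    [0, L); rows are taken mod L).  Assumes slope >= 0 towards lo and
    <= 0 towards hi."""
    for _ in range(_BISECT_STEPS):
        if hi - lo <= 4:
            break
        mid = (lo + hi) // 2
        val = slope_at(mid % L)
        if abs(val) <= COLLISION_SLOPE_THRESHOLD:
            return mid % L
        if val > 0:
            lo = mid
        else:
            hi = mid
    return ((lo + hi) // 2) % L
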