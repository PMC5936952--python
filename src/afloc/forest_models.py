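"""Training-corpus generation and the four random-forest models.

The localization algorithm uses four forests trained on simulated
fibrillating tissues: two binary classifiers deciding whether the probe
sits on the driver's x-band / y-band (the column/row range through the
circuit), and two probabilistic locators whose classes are signed
displacement bins (driver minus probe, 5-cell bins) along x and y.
Class probabilities are ensemble vote fractions, P_i = k_i / k with
k = sum_i k_i over the trees' votes.

Displacement classes (rather than absolute coordinates) are used
because the gradient features are translation-invariant across the
row-periodic tissue; the probe's known position converts a displacement
distribution into per-column probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import lattice_model as lm
from .electrogram import (
    DEFAULT_DURATION,
    ElectrogramEngine,
    MultiProbe,
    make_multiprobe,
    record_probes,
)
from .features import FEATURE_VECTOR_NAMES, SCHEMA_VERSION, feature_vector

logger = logging.getLogger(__name__)

# Cells per displacement class.  The x-extent of a circuit (30 columns)
# dwarfs the x bin, so coarse x bins cost nothing, while the y-locator
# must resolve the 2-row band and gets near-cell resolution.  Finer
# bins multiply the forests' per-node class arrays, so each axis gets
# the coarsest width its job allows.
BIN_WIDTH_X = 5
BIN_WIDTH_Y = 2
N_ELECTRODES_PER_PROBE = 9
DEFAULT_PROBES_PER_TISSUE = 64

LABEL_COLUMNS = (
    "probe_row",
    "probe_col",
    "driver_row",
    "driver_col",
    "dx",
    "dy",
    "on_x_axis",
    "on_y_axis",
    "on_circuit",
)


def n_electrode_recordings(
    n_tissues: int,
    probes_per_tissue: int = DEFAULT_PROBES_PER_TISSUE,
    electrodes_per_probe: int = N_ELECTRODES_PER_PROBE,
) -> int:
    """Total single-electrode recordings in a corpus (accounting identity)."""
    return n_tissues * probes_per_tissue * electrodes_per_probe


def displacement_bin(d: float | np.ndarray, width: int) -> np.ndarray | int:
    """Signed displacement -> class label (bin of the given width,
    centred on multiples of the width)."""
    b = np.round(np.asarray(d, dtype=float) / width).astype(int)
    return int(b) if b.ndim == 0 else b


def bin_midpoint(label: int | np.ndarray, width: int) -> np.ndarray | float:
    """Class label -> displacement at the bin centre."""
    return np.asarray(label) * float(width)


def signed_row_displacement(driver_row: float, probe_row: float, L: int) -> float:
    """Minimum-image signed row displacement driver - probe, in [-L/2, L/2)."""
    return float((driver_row - probe_row + L / 2) % L - L / 2)


def probe_grid_centres(
    L: int,
    probes_per_tissue: int = DEFAULT_PROBES_PER_TISSUE,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Uniform n x n arrangement of multiprobe centres (n^2 probes):
    rows evenly spaced on the periodic circle, columns evenly spaced
    within the valid placement range.  With an rng, the whole grid gets
    a random phase per call so that, across many tissues, every centre
    position is covered rather than the same n^2 points."""
    n = int(round(np.sqrt(probes_per_tissue)))
    if n * n != probes_per_tissue:
        raise ValueError("probes_per_tissue must be a perfect square")
    half = 3
    u_row = u_col = 0.0
    if rng is not None:
        u_row, u_col = rng.random(2)
    rows = ((np.arange(n) + 0.5 + u_row) * L / n).astype(int) % L
    span = L - 2 * half  # valid centre columns [half, L-1-half]
    cols = half + ((np.arange(n) + 0.5 + u_col) * span / n).astype(int) % span
    return [(int(r), int(c)) for r in rows for c in cols]


def overlaps_x(probe_col: int, circuit: lm.CircuitSpec) -> bool:
    c_lo, c_hi = circuit.col_range
    return probe_col + 3 >= c_lo and probe_col - 3 <= c_hi


def overlaps_y(probe_row: int, circuit: lm.CircuitSpec, L: int) -> bool:
    for row in circuit.rows:
        d = abs((row % L) - probe_row)
        if min(d, L - d) <= 3:
            return True
    return False


def probe_on_circuit(centre: tuple[int, int], circuit: lm.CircuitSpec, L: int) -> bool:
    """The probe is on the circuit when any footprint cell lies in its
    7x7 region; for the rectangular footprint this is the conjunction
    of the per-axis range overlaps."""
    return overlaps_x(centre[1], circuit) and overlaps_y(centre[0], circuit, L)


def _tissue_rows(
    config: lm.ModelConfig,
    rng: np.random.Generator,
    probes: list[MultiProbe] | None,
    probes_per_tissue: int,
    duration: int,
    tissue_index: int,
    max_attempts: int = 5,
) -> pd.DataFrame:
    """Simulate one tissue with one random circuit and label every probe."""
    L = config.L
    for attempt in range(max_attempts):
        tissue = lm.build_tissue(config, rng)
        anchor = lm.sample_anchor(config, rng)
        circuit = lm.insert_circuit(tissue, anchor)
        try:
            sim, _ = lm.initialize_af(tissue, circuit, rng=rng)
            break
        except lm.InitializationError:
            logger.warning("initialization failed (attempt %d); resampling tissue", attempt + 1)
    else:
        raise lm.InitializationError("repeated initialization failures")

    if probes is None:
        probes = [
            make_multiprobe(c, L)
            for c in probe_grid_centres(L, probes_per_tissue, rng=rng)
        ]
    engine = ElectrogramEngine(tissue)
    records = record_probes(sim, probes, duration=duration, engine=engine)

    d_row, d_col = circuit.centre(L)
    rows = []
    for probe, rec in zip(probes, records):
        fv = feature_vector(rec)
        pr, pc = probe.centre
        row = dict(zip(FEATURE_VECTOR_NAMES, fv))
        row.update(
            tissue_index=tissue_index,
            probe_row=pr,
            probe_col=pc,
            driver_row=d_row,
            driver_col=d_col,
            dx=d_col - pc,
            dy=signed_row_displacement(d_row, pr, L),
            on_x_axis=overlaps_x(pc, circuit),
            on_y_axis=overlaps_y(pr, circuit, L),
            on_circuit=probe_on_circuit(probe.centre, circuit, L),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def generate_training_set(
    n_tissues: int,
    probes_per_tissue: int = DEFAULT_PROBES_PER_TISSUE,
    config: lm.ModelConfig | None = None,
    rng: np.random.Generator | int | None = None,
    duration: int = DEFAULT_DURATION,
) -> pd.DataFrame:
    """Simulate ``n_tissues`` fibrillating tissues, each with one random
    circuit and a uniform grid of multiprobes recording two cycles, and
    return one labelled feature row per probe."""
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    config = config or lm.ModelConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    frames = [
        _tissue_rows(config, rng, None, probes_per_tissue, duration, i)
        for i in range(n_tissues)
    ]
    table = pd.concat(frames, ignore_index=True)
    table.attrs["n_tissues"] = n_tissues
    table.attrs["probes_per_tissue"] = probes_per_tissue
    table.attrs["n_electrode_recordings"] = n_electrode_recordings(
        n_tissues, probes_per_tissue
    )
    table.attrs["schema_version"] = SCHEMA_VERSION
    return table


@dataclass
class ModelBundle:
    """The four trained forests plus the feature schema they share."""

    clf_x: RandomForestClassifier
    clf_y: RandomForestClassifier
    prob_x: RandomForestClassifier
    prob_y: RandomForestClassifier
    feature_names: tuple[str, ...] = FEATURE_VECTOR_NAMES
    schema_version: int = SCHEMA_VERSION
    bin_width_x: int = BIN_WIDTH_X
    bin_width_y: int = BIN_WIDTH_Y
    meta: dict = field(default_factory=dict)

    def models(self) -> dict[str, RandomForestClassifier]:
        return {
            "clf_x": self.clf_x,
            "clf_y": self.clf_y,
            "prob_x": self.prob_x,
            "prob_y": self.prob_y,
        }

    def _check(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature vector length {x.shape[1]} does not match schema "
                f"({len(self.feature_names)} features, version {self.schema_version})"
            )
        return x

    def on_axis(self, features: np.ndarray) -> tuple[bool, bool]:
        x = self._check(features)
        return bool(self.clf_x.predict(x)[0]), bool(self.clf_y.predict(x)[0])

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a ModelBundle")
        if bundle.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"bundle schema version {bundle.schema_version} != {SCHEMA_VERSION}"
            )
        return bundle


# Forest settings, chosen on a held-out validation corpus.  The on-axis
# classifiers need regularized leaves (otherwise deep trees memorize and
# class weighting has no effect on predictions) plus an extra factor on
# the positive-class weight: on-band rows are rare (~18% for x, ~4% for
# y) and the cost of missing the driver band dominates the cost of a
# false alarm, which the far-field feature contrast keeps negligible.
CLASSIFIER_POSITIVE_BOOST = 3.0
DEFAULT_CLASSIFIER_HYPERPARAMS = dict(
    n_estimators=200,
    max_depth=None,
    min_samples_leaf=10,
    max_features="sqrt",
    bootstrap=True,
    n_jobs=1,
)
DEFAULT_LOCATOR_X_HYPERPARAMS = dict(
    n_estimators=100,
    max_depth=None,
    min_samples_leaf=20,
    max_features="sqrt",
    bootstrap=True,
    n_jobs=1,
)
DEFAULT_LOCATOR_Y_HYPERPARAMS = dict(
    n_estimators=100,
    max_depth=None,
    min_samples_leaf=10,
    max_features="sqrt",
    bootstrap=True,
    n_jobs=1,
)


def _boosted_balanced_weight(y: np.ndarray, boost: float) -> dict:
    pos = int(np.count_nonzero(y))
    neg = y.size - pos
    if pos == 0 or neg == 0:
        return {False: 1.0, True: 1.0}
    return {False: 1.0, True: boost * neg / pos}


def train_models(
    table: pd.DataFrame,
    hyperparams: dict | None = None,
    rng: int | None = 0,
) -> ModelBundle:
    """Fit the two on-axis classifiers (class-weighted: on-band rows are
    rare) and the two displacement locators on a labelled corpus."""
    X = table[list(FEATURE_VECTOR_NAMES)].to_numpy(dtype=float)
    y_on_x = table["on_x_axis"].to_numpy(bool)
    y_on_y = table["on_y_axis"].to_numpy(bool)
    targets = {
        "clf_x": (y_on_x, _boosted_balanced_weight(y_on_x, CLASSIFIER_POSITIVE_BOOST)),
        "clf_y": (y_on_y, _boosted_balanced_weight(y_on_y, CLASSIFIER_POSITIVE_BOOST)),
        "prob_x": (displacement_bin(table["dx"].to_numpy(float), BIN_WIDTH_X), None),
        "prob_y": (displacement_bin(table["dy"].to_numpy(float), BIN_WIDTH_Y), None),
    }
    fitted = {}
    hp_used = {}
    for i, (name, (y, weight)) in enumerate(targets.items()):
        if np.unique(y).size < 2:
            raise ValueError(f"target {name} is degenerate (single class)")
        defaults = {
            "clf_x": DEFAULT_CLASSIFIER_HYPERPARAMS,
            "clf_y": DEFAULT_CLASSIFIER_HYPERPARAMS,
            "prob_x": DEFAULT_LOCATOR_X_HYPERPARAMS,
            "prob_y": DEFAULT_LOCATOR_Y_HYPERPARAMS,
        }
        hp = dict(defaults[name])
        if hyperparams:
            hp.update(hyperparams)
        hp_used[name] = hp
        model = RandomForestClassifier(
            class_weight=weight,
            random_state=None if rng is None else int(rng) + i,
            **hp,
        )
        model.fit(X, y)
        fitted[name] = model
    return ModelBundle(
        **fitted,
        meta={
            "n_rows": len(table),
            "n_tissues": table.attrs.get("n_tissues"),
            "seed": rng,
            "hyperparams": hp_used,
        },
    )


def vote_probabilities(counts: np.ndarray) -> np.ndarray:
    """Vote counts -> class probabilities, P_i = k_i / k."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("vote counts must be non-negative")
    k = counts.sum()
    if k == 0:
        raise ValueError("no votes cast")
    return counts / k


def class_probabilities(
    model: RandomForestClassifier, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble vote-fraction distribution over the model's classes for
    a single feature vector: each tree casts one vote, P_i = k_i / k."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature vector length {x.shape[1]} does not match model "
            f"({model.n_features_in_})"
        )
    counts = np.zeros(len(model.classes_))
    for tree in model.estimators_:
        counts[int(tree.predict(x)[0])] += 1
    return model.classes_.copy(), vote_probabilities(counts)


def feature_importance(
    model: RandomForestClassifier,
    names: tuple[str, ...] = FEATURE_VECTOR_NAMES,
) -> list[tuple[str, float]]:
    """Mean impurity-decrease (Gini) importances, descending; sums to 1."""
    imp = model.feature_importances_
    order = np.argsort(imp)[::-1]
    return [(names[i], float(imp[i])) for i in order]
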