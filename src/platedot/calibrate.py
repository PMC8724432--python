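"""Measurement containers and data calibration.

Continuous-wave DOT amplitudes are only meaningful relative to a model
prediction: per-channel gains, coupling losses and source power all enter
multiplicatively.  The classical fix is a *reference phantom* scan — a
homogeneous object with the task's shape and background optics — giving

    calibrated = task / reference * predicted            (reference calibration)

which cancels any per-channel multiplicative gain exactly.  The
self-calibration strategy replaces the physical reference with a *virtual
homogeneous reference* built from the task scan itself: within each
SD-distance class the maximum amplitude is the measurement least affected by
localized absorbers, so assigning every member of class k the class maximum
produces an estimate of what a homogeneous medium would have returned:

    estimated(i, j) = max over class of d_ij of task amplitudes
    calibrated      = task / estimated * predicted       (self-calibration)

Both paths are exact in the noiseless homogeneous limit and differ only by
how well the class maxima approximate the homogeneous reference, quantified
by :func:`mean_relative_error`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivisionHazardError, InvalidInputError, NoDataError
from .probe import DistanceClass, SDPair

#: Amplitudes at or below this are treated as zero in calibration denominators.
AMPLITUDE_FLOOR = 1e-30

ROLES = ("task", "reference", "predicted", "estimated", "calibrated")


@dataclass
class MeasurementSet:
    """Per-wavelength transmission amplitudes keyed by (source, detector).

    Arrays are aligned: entry p describes the pair
    ``(source_index[p], detector_index[p])`` (1-based).  ``excluded`` marks
    pairs removed by coverage / distance / boundary selection; excluded
    amplitudes are carried but never used by calibration or reconstruction.
    """

    wavelength_nm: float
    role: str
    source_index: np.ndarray
    detector_index: np.ndarray
    amplitude: np.ndarray
    excluded: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise InvalidInputError(f"unknown role '{self.role}'; expected one of {ROLES}")
        self.source_index = np.asarray(self.source_index, dtype=np.int64)
        self.detector_index = np.asarray(self.detector_index, dtype=np.int64)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = len(self.source_index)
        if not (len(self.detector_index) == len(self.amplitude) == len(self.excluded) == n):
            raise InvalidInputError("measurement arrays have mismatched lengths")
        self._index = {
            (int(i), int(j)): p
            for p, (i, j) in enumerate(zip(self.source_index, self.detector_index))
        }

    @classmethod
    def from_pairs(cls, pairs, amplitudes, wavelength_nm, role, meta=None):
        """Build from a list of :class:`~platedot.probe.SDPair` and aligned amplitudes."""
        amplitudes = np.asarray(amplitudes, dtype=float)
        if len(amplitudes) != len(pairs):
            raise InvalidInputError("amplitudes not aligned with pair list")
        return cls(
            wavelength_nm=wavelength_nm,
            role=role,
            source_index=np.array([p.source_index for p in pairs]),
            detector_index=np.array([p.detector_index for p in pairs]),
            amplitude=amplitudes,
            excluded=np.array([p.excluded for p in pairs]),
            meta=dict(meta or {}),
        )

    def __len__(self) -> int:
        return len(self.amplitude)

    @property
    def n_retained(self) -> int:
        return int((~self.excluded).sum())

    def position(self, source_index: int, detector_index: int) -> int:
        try:
            return self._index[(int(source_index), int(detector_index))]
        except KeyError:
            raise InvalidInputError(
                f"pair ({source_index}, {detector_index}) not in measurement set"
            ) from None

    def amplitude_at(self, source_index: int, detector_index: int) -> float:
        """Amplitude of one pair, by 1-based indices."""
        return float(self.amplitude[self.position(source_index, detector_index)])

    def retained_keys(self) -> list[tuple[int, int]]:
        return [
            (int(i), int(j))
            for i, j, e in zip(self.source_index, self.detector_index, self.excluded)
            if not e
        ]

    def with_amplitudes(self, amplitude, role=None, meta=None) -> "MeasurementSet":
        out = replace(
            self,
            amplitude=np.asarray(amplitude, dtype=float),
            role=role or self.role,
        )
        if meta is not None:
            out.meta = {**self.meta, **meta}
        return out

    def restrict_to(self, keys, reason_meta: str | None = None) -> "MeasurementSet":
        """Copy with every pair not in ``keys`` flagged as excluded."""
        keep = set((int(i), int(j)) for i, j in keys)
        excluded = np.array(
            [
                e or (int(i), int(j)) not in keep
                for i, j, e in zip(self.source_index, self.detector_index, self.excluded)
            ]
        )
        out = replace(self, excluded=excluded)
        if reason_meta:
            out.meta = {**self.meta, "restriction": reason_meta}
        return out


def _aligned(*sets: MeasurementSet):
    """Shared retained keys of several sets plus aligned amplitude arrays.

    All sets must have the same wavelength and identical retained pair sets.
    """
    base = sets[0]
    keys = base.retained_keys()
    if not keys:
        raise NoDataError("no retained pairs")
    keyset = set(keys)
    for other in sets[1:]:
        if other.wavelength_nm != base.wavelength_nm:
            raise InvalidInputError(
                f"wavelength mismatch: {other.wavelength_nm} vs {base.wavelength_nm}"
            )
        if set(other.retained_keys()) != keyset:
            raise InvalidInputError(
                f"retained pair sets differ between roles "
                f"'{base.role}' and '{other.role}'"
            )
    arrays = [
        np.array([s.amplitude_at(i, j) for (i, j) in keys]) for s in sets
    ]
    return keys, arrays


def _check_denominator(values: np.ndarray, keys, role: str):
    bad = np.where(values <= AMPLITUDE_FLOOR)[0]
    if len(bad):
        i, j = keys[bad[0]]
        raise DivisionHazardError(
            f"{role} amplitude at pair ({i}, {j}) is zero/below floor "
            f"({values[bad[0]]:.3g} <= {AMPLITUDE_FLOOR:g})",
            pair=(i, j),
        )


def _ratio_calibrate(task, denominator, predicted, kind: str) -> MeasurementSet:
    keys, (a_task, a_den, a_pre) = _aligned(task, denominator, predicted)
    _check_denominator(a_den, keys, denominator.role)
    ratio = dict(zip(keys, a_task / a_den * a_pre))
    out_amp = np.full(len(task), np.nan)
    for p, (i, j, e) in enumerate(
        zip(task.source_index, task.detector_index, task.excluded)
    ):
        if not e:
            out_amp[p] = ratio[(int(i), int(j))]
    return task.with_amplitudes(
        out_amp, role="calibrated", meta={"calibration": kind}
    )


def reference_calibrate(
    task: MeasurementSet, reference: MeasurementSet, predicted: MeasurementSet
) -> MeasurementSet:
    """Reference-phantom calibration: ``task / reference * predicted`` pairwise.

    Per-channel multiplicative gains applied identically to the task and
    reference scans cancel exactly.  Excluded pairs propagate as excluded.
    """
    return _ratio_calibrate(task, reference, predicted, kind="reference")


def self_calibrate(
    task: MeasurementSet, estimated: MeasurementSet, predicted: MeasurementSet
) -> MeasurementSet:
    """Data self-calibration: ``task / estimated * predicted`` pairwise.

    ``estimated`` is the virtual homogeneous reference from
    :func:`build_virtual_reference`; since it dominates the task pairwise, the
    calibrated amplitudes never exceed the prediction.  A global scale on the
    task (source power, integration time) cancels exactly.
    """
    return _ratio_calibrate(task, estimated, predicted, kind="self")


def build_virtual_reference(
    task: MeasurementSet, classes: list[DistanceClass]
) -> MeasurementSet:
    """Construct the virtual homogeneous reference from per-class maxima.

    Every member of distance class k receives the class's maximum task
    amplitude.  Exclusions and boundary selection must already be reflected in
    ``classes``/``task``: the classes must cover exactly the task's retained
    pairs.  The result is the pointwise-smallest class-constant set that
    dominates the task.
    """
    if not classes or all(len(c) == 0 for c in classes):
        raise NoDataError("no retained distance classes")
    est = {}
    for cls in classes:
        amps = np.array(
            [task.amplitude_at(p.source_index, p.detector_index) for p in cls.members]
        )
        cls.class_max = float(amps.max())
        mean = float(amps.mean())
        cls.cov = float(amps.std() / mean) if mean > 0 else float("inf")
        for p in cls.members:
            est[p.key] = cls.class_max
    if set(est.keys()) != set(task.retained_keys()):
        raise InvalidInputError(
            "distance classes do not cover the task's retained pair set; "
            "apply exclusions/selection to the task first"
        )
    out_amp = np.full(len(task), np.nan)
    for p, (i, j, e) in enumerate(
        zip(task.source_index, task.detector_index, task.excluded)
    ):
        if not e:
            out_amp[p] = est[(int(i), int(j))]
    return task.with_amplitudes(out_amp, role="estimated", meta={"virtual_reference": True})


def mean_relative_error(
    estimated: MeasurementSet, reference: MeasurementSet
) -> float:
    """Mean over retained pairs of |estimated - reference| / reference.

    This is the fidelity metric for the virtual reference: it vanishes when
    the class maxima reproduce the homogeneous reference exactly.
    """
    keys, (a_est, a_ref) = _aligned(estimated, reference)
    _check_denominator(a_ref, keys, reference.role)
    return float(np.mean(np.abs(a_est - a_ref) / a_ref))


def relative_error_by_class(
    estimated: MeasurementSet,
    reference: MeasurementSet,
    classes: list[DistanceClass],
) -> dict[float, float]:
    """Per-distance-class mean relative error, keyed by d_k."""
    out = {}
    for cls in classes:
        if not cls.members:
            continue
        a_est = np.array(
            [estimated.amplitude_at(*p.key) for p in cls.members]
        )
        a_ref = np.array(
            [reference.amplitude_at(*p.key) for p in cls.members]
        )
        _check_denominator(a_ref, [p.key for p in cls.members], reference.role)
        out[cls.d_k] = float(np.mean(np.abs(a_est - a_ref) / a_ref))
    if not out:
        raise NoDataError("no populated distance classes")
    return out
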