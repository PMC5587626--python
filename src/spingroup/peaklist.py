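"""Core peak-list domain types and file I/O.

A peak list is the tabular output of one NMR experiment: one row per
resonance peak, one chemical-shift coordinate (ppm) per spectral dimension.
Three on-disk dialects are supported:

* ``sparky`` -- whitespace columns ``Assignment  w1  w2 [w3 [w4]]`` with a
  one-line header; unassigned peaks carry the conventional ``?-?-?`` label.
* ``autoassign`` -- tab-separated table with a one-line header
  ``Index<TAB>w1..wN<TAB>Assignment``.
* ``json`` -- a self-describing object that additionally round-trips
  spectrum metadata, comparable dimensions and truth-group labels.

The analysis algorithms (registration, grouping) only ever consume the
in-memory :class:`PeakList`, so the dialects are interchangeable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "Peak",
    "PeakList",
    "DimensionStats",
    "PeakListFormatError",
    "read_peaklist",
    "write_peaklist",
    "FORMATS",
]

FORMATS = ("sparky", "autoassign", "json")

#: Sparky convention for an unassigned peak label.
UNASSIGNED_LABEL = "?-?-?"


class PeakListFormatError(ValueError):
    """Raised when a peak-list file does not parse under the named dialect."""


@dataclass
class Peak:
    """One multidimensional resonance position.

    Parameters
    ----------
    index:
        Position of the peak within its owning list (``>= 0``).
    shifts:
        Chemical shift per spectral dimension, in ppm.
    label:
        Optional assignment string, e.g. ``"A45N-CA-H"``.
    truth_group:
        True spin-system id; only present for simulated/assigned peaks.
    """

    index: int
    shifts: tuple[float, ...]
    label: str | None = None
    truth_group: int | None = None

    def __post_init__(self) -> None:
        self.shifts = tuple(float(s) for s in self.shifts)
        if self.index < 0:
            raise ValueError(f"peak index must be >= 0, got {self.index}")
        if not self.shifts:
            raise ValueError("peak must have at least one dimension")
        for s in self.shifts:
            if not math.isfinite(s):
                raise ValueError(f"non-finite chemical shift {s!r}")

    @property
    def ndim(self) -> int:
        return len(self.shifts)


@dataclass
class PeakList:
    """Ordered peaks plus spectrum metadata.

    ``comparable_dims`` names the dimensions shared by all peaks of one spin
    system (amide H and N for HN(CO)CACB-type lists; N and CA for
    NCACX-type lists) and therefore usable for matching and grouping; its
    length is the number of degrees of freedom ``df`` of the chi-square
    statistics downstream.
    """

    name: str
    dim_labels: tuple[str, ...]
    peaks: list[Peak] = field(default_factory=list)
    comparable_dims: tuple[int, ...] = ()
    spectrum_type: str = ""

    def __post_init__(self) -> None:
        self.dim_labels = tuple(str(d) for d in self.dim_labels)
        self.comparable_dims = tuple(int(d) for d in self.comparable_dims)
        if not self.dim_labels:
            raise ValueError("peak list needs at least one dimension label")
        if not self.comparable_dims:
            # default: all dimensions comparable
            self.comparable_dims = tuple(range(self.ndim))
        self._validate()

    def _validate(self) -> None:
        ndim = self.ndim
        if len(set(self.comparable_dims)) != len(self.comparable_dims):
            raise ValueError("comparable_dims contains duplicates")
        if any(d < 0 or d >= ndim for d in self.comparable_dims):
            raise ValueError(
                f"comparable_dims {self.comparable_dims} out of range for {ndim} dims"
            )
        for p in self.peaks:
            if p.ndim != ndim:
                raise PeakListFormatError(
                    f"peak {p.index} has {p.ndim} dimensions, list has {ndim}"
                )

    @property
    def ndim(self) -> int:
        return len(self.dim_labels)

    @property
    def df(self) -> int:
        """Degrees of freedom: the number of comparable dimensions."""
        return len(self.comparable_dims)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def comparable_shifts(self, i: int) -> tuple[float, ...]:
        """Shifts of peak ``i`` restricted to the comparable dimensions."""
        p = self.peaks[i]
        return tuple(p.shifts[d] for d in self.comparable_dims)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "PeakList":
        """New list holding the selected peaks, re-indexed from 0.

        ``truth_group`` and labels are carried over so evaluation remains
        possible on the subset; original indices are not preserved (use the
        returned order to map back).
        """
        peaks = [
            Peak(k, self.peaks[i].shifts, self.peaks[i].label, self.peaks[i].truth_group)
            for k, i in enumerate(indices)
        ]
        return PeakList(
            name=name or f"{self.name}-subset",
            dim_labels=self.dim_labels,
            peaks=peaks,
            comparable_dims=self.comparable_dims,
            spectrum_type=self.spectrum_type,
        )

    def truth_groups(self) -> list[int | None]:
        return [p.truth_group for p in self.peaks]


@dataclass
class DimensionStats:
    """Per-dimension registration statistics over matched peak pairs.

    ``offsets[l]`` is the translation (ppm) that moves the input list onto
    the root list in comparable dimension ``l``; it is identically zero in
    self-registration mode, where no translation is modelled.  ``stds[l]``
    estimates the per-peak positional standard deviation in that dimension.
    """

    offsets: tuple[float, ...]
    stds: tuple[float, ...]
    n_matched: int
    iterations: int

    def __post_init__(self) -> None:
        self.offsets = tuple(float(o) for o in self.offsets)
        self.stds = tuple(float(s) for s in self.stds)
        if any(s < 0 for s in self.stds):
            raise ValueError("standard deviations must be non-negative")
        if self.n_matched < 0:
            raise ValueError("n_matched must be >= 0")


# ---------------------------------------------------------------------------
# File I/O


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise PeakListFormatError(
            f"{path}:{lineno}: cannot parse chemical shift {token!r}"
        ) from None
    if not math.isfinite(v):
        raise PeakListFormatError(f"{path}:{lineno}: non-finite chemical shift {token!r}")
    return v


def _read_sparky(path: Path) -> PeakList:
    peaks: list[Peak] = []
    ndim: int | None = None
    dim_labels: tuple[str, ...] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if lineno == 1 and tokens and tokens[0].lower() == "assignment":
            dim_labels = tuple(t.lstrip("w") for t in tokens[1:])
            continue
        if len(tokens) < 3:
            raise PeakListFormatError(f"{path}:{lineno}: expected label + >=2 shifts")
        label = tokens[0]
        shifts = [_parse_float(t, str(path), lineno) for t in tokens[1:]]
        if ndim is None:
            ndim = len(shifts)
        elif len(shifts) != ndim:
            raise PeakListFormatError(
                f"{path}:{lineno}: peak has {len(shifts)} dimensions, expected {ndim}"
            )
        peaks.append(
            Peak(
                len(peaks),
                tuple(shifts),
                None if label == UNASSIGNED_LABEL else label,
            )
        )
    if ndim is None:
        # header-only / empty file: dimensionality from header if present
        if dim_labels:
            ndim = len(dim_labels)
        else:
            raise PeakListFormatError(f"{path}: empty file with no header")
    if dim_labels is None or len(dim_labels) != ndim:
        dim_labels = tuple(f"w{i+1}" for i in range(ndim))
    return PeakList(name=path.stem, dim_labels=dim_labels, peaks=peaks)


def _write_sparky(pl: PeakList, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("Assignment " + " ".join(f"w{i+1}" for i in range(pl.ndim)) + "\n")
        for p in pl.peaks:
            label = p.label if p.label is not None else UNASSIGNED_LABEL
            cols = " ".join(f"{s:10.4f}" for s in p.shifts)
            fh.write(f"{label:>17s} {cols}\n")


def _read_autoassign(path: Path) -> PeakList:
    peaks: list[Peak] = []
    ndim: int | None = None
    dim_labels: tuple[str, ...] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tokens = line.split("\t")
        if lineno == 1 and tokens and tokens[0].lower() == "index":
            dim_labels = tuple(t.lstrip("w") for t in tokens[1:-1])
            continue
        if len(tokens) < 3:
            raise PeakListFormatError(
                f"{path}:{lineno}: expected Index<TAB>shifts...<TAB>Assignment"
            )
        shifts = [_parse_float(t, str(path), lineno) for t in tokens[1:-1]]
        label = tokens[-1].strip()
        if ndim is None:
            ndim = len(shifts)
        elif len(shifts) != ndim:
            raise PeakListFormatError(
                f"{path}:{lineno}: peak has {len(shifts)} dimensions, expected {ndim}"
            )
        peaks.append(
            Peak(
                len(peaks),
                tuple(shifts),
                None if label in ("", UNASSIGNED_LABEL) else label,
            )
        )
    if ndim is None:
        if dim_labels:
            ndim = len(dim_labels)
        else:
            raise PeakListFormatError(f"{path}: empty file with no header")
    if dim_labels is None or len(dim_labels) != ndim:
        dim_labels = tuple(f"w{i+1}" for i in range(ndim))
    return PeakList(name=path.stem, dim_labels=dim_labels, peaks=peaks)


def _write_autoassign(pl: PeakList, path: Path) -> None:
    with open(path, "w") as fh:
        header = ["Index"] + [f"w{i+1}" for i in range(pl.ndim)] + ["Assignment"]
        fh.write("\t".join(header) + "\n")
        for p in pl.peaks:
            label = p.label if p.label is not None else UNASSIGNED_LABEL
            cols = [str(p.index + 1)] + [f"{s:.4f}" for s in p.shifts] + [label]
            fh.write("\t".join(cols) + "\n")


def _read_json(path: Path) -> PeakList:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PeakListFormatError(f"{path}:{exc.lineno}: invalid JSON: {exc.msg}") from None
    if not isinstance(obj, dict) or "peaks" not in obj:
        raise PeakListFormatError(f"{path}: JSON peak list must be an object with 'peaks'")
    dims = obj.get("dims")
    if dims is None:
        raise PeakListFormatError(f"{path}: missing 'dims'")
    peaks = []
    for k, rec in enumerate(obj["peaks"]):
        shifts = rec.get("shifts")
        if shifts is None:
            raise PeakListFormatError(f"{path}: peak {k} missing 'shifts'")
        if len(shifts) != len(dims):
            raise PeakListFormatError(
                f"{path}: peak {k} has {len(shifts)} dimensions, expected {len(dims)}"
            )
        peaks.append(Peak(k, tuple(shifts), rec.get("label"), rec.get("truth_group")))
    return PeakList(
        name=obj.get("name", path.stem),
        dim_labels=tuple(dims),
        peaks=peaks,
        comparable_dims=tuple(obj.get("comparable_dims", ())) or tuple(range(len(dims))),
        spectrum_type=obj.get("spectrum_type", ""),
    )


def _write_json(pl: PeakList, path: Path) -> None:
    obj = {
        "name": pl.name,
        "spectrum_type": pl.spectrum_type,
        "dims": list(pl.dim_labels),
        "comparable_dims": list(pl.comparable_dims),
        "peaks": [
            {"shifts": list(p.shifts), "label": p.label, "truth_group": p.truth_group}
            for p in pl.peaks
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


_READERS = {"sparky": _read_sparky, "autoassign": _read_autoassign, "json": _read_json}
_WRITERS = {"sparky": _write_sparky, "autoassign": _write_autoassign, "json": _write_json}


def read_peaklist(path: str | Path, format: str = "sparky") -> PeakList:
    """Read a peak-list file in the named dialect.

    Raises :class:`PeakListFormatError` naming the offending line on parse
    failure or inconsistent dimensionality.
    """
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return _READERS[format](Path(path))


def write_peaklist(pl: PeakList, path: str | Path, format: str = "sparky") -> None:
    """Write a peak list; text dialects round shifts to 4 decimal places (ppm),
    JSON keeps full precision plus metadata."""
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    _WRITERS[format](pl, Path(path))
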