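"""Declarative spectrum descriptions for peak-list simulation.

A triple-resonance experiment is described by its dimensions, each carrying
one or more alternative resonance classes (``CA``, ``CB``, ``N``, ...) at a
relative residue position (−1 = preceding residue, 0 = own residue, +1 =
following residue).  A dimension with several alternatives multiplies the
peaks per spin system: HN(CO)CACB has dimensions ``{H:0, N:0, CA|CB:−1}``
and hence two peaks per spin system, except where the preceding residue is
a glycine (no CB).

Descriptions are loaded from a small JSON dialect::

    {
      "name": "HNcoCACB",
      "dimensions": [
        {"label": "H",     "classes": [{"resonance_class": "H",  "relative_position": 0}]},
        {"label": "N",     "classes": [{"resonance_class": "N",  "relative_position": 0}]},
        {"label": "CA/CB", "classes": [{"resonance_class": "CA", "relative_position": -1},
                                       {"resonance_class": "CB", "relative_position": -1}]}
      ],
      "comparable_dims": [0, 1]
    }

The pseudo-class ``CX`` expands to the carbons CA, CB and CO of the target
residue (a documented simplification of full side-chain coverage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

__all__ = [
    "ResonanceAlternative",
    "DimensionSpec",
    "SpectrumDescription",
    "SpectrumConfigError",
    "load_spectrum_description",
    "builtin_description",
    "BUILTIN_SPECTRA",
]

#: Recognized atom-class tokens.
RESONANCE_CLASSES = frozenset({"H", "N", "CA", "CB", "CO", "CX"})

#: What the CX pseudo-class expands to.
CX_EXPANSION = ("CA", "CB", "CO")


class SpectrumConfigError(ValueError):
    """Raised for malformed spectrum-description configs."""


@dataclass(frozen=True)
class ResonanceAlternative:
    resonance_class: str
    relative_position: int

    def __post_init__(self) -> None:
        if self.resonance_class not in RESONANCE_CLASSES:
            raise SpectrumConfigError(
                f"unknown resonance class {self.resonance_class!r}; "
                f"expected one of {sorted(RESONANCE_CLASSES)}"
            )


@dataclass(frozen=True)
class DimensionSpec:
    label: str
    alternatives: tuple[ResonanceAlternative, ...]

    def expanded(self) -> tuple[ResonanceAlternative, ...]:
        """Alternatives with the CX pseudo-class expanded to real carbons."""
        out: list[ResonanceAlternative] = []
        for alt in self.alternatives:
            if alt.resonance_class == "CX":
                out.extend(
                    ResonanceAlternative(c, alt.relative_position) for c in CX_EXPANSION
                )
            else:
                out.append(alt)
        return tuple(out)


@dataclass(frozen=True)
class SpectrumDescription:
    """Declarative definition of one experiment's peak pattern."""

    name: str
    dimensions: tuple[DimensionSpec, ...]
    comparable_dims: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise SpectrumConfigError("spectrum description needs >= 1 dimension")
        if not self.comparable_dims:
            object.__setattr__(self, "comparable_dims", self._default_comparable())
        nd = len(self.dimensions)
        if any(d < 0 or d >= nd for d in self.comparable_dims):
            raise SpectrumConfigError("comparable_dims out of range")

    def _default_comparable(self) -> tuple[int, ...]:
        # dimensions with a single unambiguous resonance class are shared by
        # all peaks of a spin system, hence comparable (H,N for HN(CO)CACB;
        # N,CA for NCACX); if every dimension is unambiguous they all are.
        single = tuple(
            i for i, d in enumerate(self.dimensions) if len(d.expanded()) == 1
        )
        return single if single else tuple(range(len(self.dimensions)))

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    def dim_labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.dimensions)

    def peak_patterns(self) -> list[tuple[ResonanceAlternative, ...]]:
        """All per-peak atom patterns: the Cartesian product of the expanded
        per-dimension alternatives, in declaration order."""
        return list(product(*(d.expanded() for d in self.dimensions)))


def _parse_description(obj: dict, fallback_name: str) -> SpectrumDescription:
    if "dimensions" not in obj:
        raise SpectrumConfigError("spectrum description is missing 'dimensions'")
    dims = []
    for k, rec in enumerate(obj["dimensions"]):
        classes = rec.get("classes")
        if not classes:
            raise SpectrumConfigError(f"dimension {k} has no 'classes'")
        alts = tuple(
            ResonanceAlternative(c["resonance_class"], int(c["relative_position"]))
            for c in classes
        )
        dims.append(DimensionSpec(rec.get("label", f"w{k+1}"), alts))
    return SpectrumDescription(
        name=obj.get("name", fallback_name),
        dimensions=tuple(dims),
        comparable_dims=tuple(obj.get("comparable_dims", ())),
    )


def load_spectrum_description(path: str | Path) -> SpectrumDescription:
    """Load a spectrum description from a JSON config file."""
    path = Path(path)
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SpectrumConfigError(f"{path}: invalid JSON: {exc.msg}") from None
    return _parse_description(obj, path.stem)


def _mk(name: str, dims: list[tuple[str, list[tuple[str, int]]]],
        comparable: tuple[int, ...] = ()) -> SpectrumDescription:
    return SpectrumDescription(
        name=name,
        dimensions=tuple(
            DimensionSpec(label, tuple(ResonanceAlternative(c, p) for c, p in alts))
            for label, alts in dims
        ),
        comparable_dims=comparable,
    )


#: Bundled experiment definitions.
BUILTIN_SPECTRA: dict[str, SpectrumDescription] = {
    "HNcoCACB": _mk(
        "HNcoCACB",
        [("H", [("H", 0)]), ("N", [("N", 0)]), ("CA/CB", [("CA", -1), ("CB", -1)])],
    ),
    "NCACX": _mk(
        "NCACX",
        [("N", [("N", 0)]), ("CA", [("CA", 0)]), ("CX", [("CX", 0)])],
    ),
    "NCOCX": _mk(
        "NCOCX",
        [("N", [("N", 0)]), ("CO", [("CO", -1)]), ("CX", [("CX", -1)])],
    ),
    "CANCOCX": _mk(
        "CANCOCX",
        [("CA", [("CA", 0)]), ("N", [("N", 0)]), ("CO", [("CO", -1)]), ("CX", [("CX", -1)])],
    ),
}


def builtin_description(name: str) -> SpectrumDescription:
    """Return a bundled spectrum description by name (e.g. ``"HNcoCACB"``)."""
    try:
        return BUILTIN_SPECTRA[name]
    except KeyError:
        raise SpectrumConfigError(
            f"no builtin spectrum {name!r}; available: {sorted(BUILTIN_SPECTRA)}"
        ) from None
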