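"""Simulated assigned peak lists with controllable positional variance.

The simulator builds "ideal" (0-variance) peak lists from assigned
chemical-shift tables through a declarative :class:`~spingroup.spectra.SpectrumDescription`,
then perturbs peak positions with Gaussian noise ``N(0, sigma)`` per
dimension.  Two variance regimes are supported: a single noise source in
every dimension, and a two-source mixture in which a random 20% of peaks
(by default) receive noise five times larger than the remaining 80% —
emulating the multiple sources of positional variance seen in experimental
peak lists.

A bundled synthetic assignment generator (:func:`synth_assignments`) draws
random protein sequences and per-atom chemical shifts from typical
per-residue-type priors, so the whole workflow runs without any external
shift database; tables parsed from real depositions can be supplied through
the same :class:`AssignedShiftTable` container.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .peaklist import Peak, PeakList, write_peaklist
from .spectra import SpectrumDescription, builtin_description

__all__ = [
    "Residue",
    "AssignedShiftTable",
    "NoiseModel",
    "SimulationGrid",
    "synth_assignments",
    "ideal_peaklist",
    "truth_groups_from_labels",
    "add_noise",
    "filter_peaklists",
    "run_grid",
    "SHIFT_PRIORS",
    "AA_FREQUENCIES",
]


# ---------------------------------------------------------------------------
# Assigned shift tables


@dataclass(frozen=True)
class Residue:
    index: int
    aa: str  # one-letter code
    shifts: dict[str, float]  # atom name -> ppm


@dataclass
class AssignedShiftTable:
    """Assigned chemical shifts for one protein chain."""

    protein_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


# Typical per-residue-type chemical shift statistics (ppm): mean, std.
# Amide H/N, CA, CB and CO priors approximating the spread of assigned
# protein shifts; glycine has no CB and proline no amide H.
_CACB = {
    # aa: (CA mean, CA std, CB mean, CB std); CB None for Gly
    "A": (53.1, 2.0, 19.0, 1.8),
    "R": (56.8, 2.3, 30.7, 1.8),
    "N": (53.5, 1.9, 38.7, 1.7),
    "D": (54.7, 2.0, 40.9, 1.6),
    "C": (58.2, 3.3, 32.8, 6.1),
    "Q": (56.6, 2.2, 29.2, 1.8),
    "E": (57.3, 2.1, 30.0, 1.7),
    "G": (45.4, 1.3, None, None),
    "H": (56.5, 2.3, 30.2, 2.1),
    "I": (61.6, 2.7, 38.6, 2.0),
    "L": (55.6, 2.1, 42.3, 1.9),
    "K": (56.9, 2.2, 32.8, 1.8),
    "M": (56.1, 2.2, 33.0, 2.2),
    "F": (58.1, 2.6, 39.9, 2.1),
    "P": (63.3, 1.5, 31.8, 1.2),
    "S": (58.7, 2.1, 63.8, 1.5),
    "T": (62.2, 2.6, 69.7, 1.6),
    "W": (57.7, 2.6, 29.9, 2.0),
    "Y": (58.1, 2.5, 39.2, 2.2),
    "V": (62.5, 2.9, 32.7, 1.8),
}

SHIFT_PRIORS: dict[str, dict[str, tuple[float, float]]] = {}
for _aa, (_ca, _cas, _cb, _cbs) in _CACB.items():
    prior: dict[str, tuple[float, float]] = {
        "CA": (_ca, _cas),
        "CO": (174.1, 1.7) if _aa == "G" else (176.5, 1.9),
        "N": (109.8, 3.3) if _aa == "G" else (119.9, 4.2),
    }
    if _cb is not None:
        prior["CB"] = (_cb, _cbs)
    if _aa != "P":  # proline lacks the amide proton
        prior["H"] = (8.30, 0.60)
    SHIFT_PRIORS[_aa] = prior

#: Approximate natural amino-acid frequencies used for random sequences.
AA_FREQUENCIES: dict[str, float] = {
    "A": 8.3, "R": 5.5, "N": 4.1, "D": 5.4, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 5.9, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.9,
}


def synth_assignments(
    n_res: int,
    seed: int,
    aa_freqs: dict[str, float] | None = None,
) -> AssignedShiftTable:
    """Draw a random assigned-shift table for a protein of ``n_res`` residues.

    The sequence is sampled from ``aa_freqs`` (defaults to approximate
    natural frequencies) and every present atom's shift from the bundled
    per-(residue type, atom) Gaussian priors.  Deterministic under ``seed``.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    freqs = aa_freqs or AA_FREQUENCIES
    aas = sorted(freqs)
    w = np.array([freqs[a] for a in aas], dtype=float)
    if w.sum() <= 0:
        raise ValueError("amino-acid frequencies must have positive mass")
    rng = np.random.default_rng(seed)
    seq = rng.choice(aas, size=n_res, p=w / w.sum())
    residues = []
    for i, aa in enumerate(seq, start=1):
        shifts = {
            atom: float(rng.normal(mu, sd))
            for atom, (mu, sd) in SHIFT_PRIORS[aa].items()
        }
        residues.append(Residue(i, str(aa), shifts))
    return AssignedShiftTable(protein_id=f"synth-{seed}", residues=residues)


# ---------------------------------------------------------------------------
# Ideal peak list generation


def _peak_label(atoms: Sequence[tuple[Residue, str]]) -> str:
    return "-".join(f"{r.aa}{r.index}{atom}" for r, atom in atoms)


def ideal_peaklist(
    table: AssignedShiftTable,
    spec: SpectrumDescription,
    missing_report: list[tuple[int, str]] | None = None,
) -> PeakList:
    """Build the 0-variance peak list a spectrum would show for ``table``.

    For every anchor residue, each peak pattern of ``spec`` (the Cartesian
    product of per-dimension resonance-class alternatives) is emitted when
    all required shifts exist.  For HN(CO)CACB this yields, per residue
    ``i`` with an amide and an existing predecessor, the peaks
    ``(H_i, N_i, CA_{i-1})`` and — unless residue ``i−1`` is glycine —
    ``(H_i, N_i, CB_{i-1})``; prolines produce no peaks.

    ``truth_group`` on every peak is the anchor residue's index, i.e. the
    true spin-system id.  Peaks sharing an anchor share all comparable-
    dimension coordinates exactly.

    If ``missing_report`` is given, (residue index, atom) entries are
    appended for required shifts that are absent for reasons other than the
    canonical glycine-CB / proline-H gaps.
    """
    by_pos = {k: r for k, r in enumerate(table.residues)}
    patterns = spec.peak_patterns()
    peaks: list[Peak] = []
    seen: dict[int, set[tuple[float, ...]]] = {}
    for pos, anchor in enumerate(table.residues):
        for pattern in patterns:
            shifts: list[float] = []
            atoms: list[tuple[Residue, str]] = []
            ok = True
            for alt in pattern:
                res = by_pos.get(pos + alt.relative_position)
                if res is None:
                    ok = False
                    break
                value = res.shifts.get(alt.resonance_class)
                if value is None:
                    benign = (alt.resonance_class == "CB" and res.aa == "G") or (
                        alt.resonance_class == "H" and res.aa == "P"
                    )
                    if not benign and missing_report is not None:
                        missing_report.append((res.index, alt.resonance_class))
                    ok = False
                    break
                shifts.append(value)
                atoms.append((res, alt.resonance_class))
            if not ok:
                continue
            tup = tuple(shifts)
            if tup in seen.setdefault(anchor.index, set()):
                continue  # degenerate pattern (e.g. CX expanding onto CA twice)
            seen[anchor.index].add(tup)
            peaks.append(
                Peak(len(peaks), tup, label=_peak_label(atoms), truth_group=anchor.index)
            )
    return PeakList(
        name=f"{table.protein_id}-{spec.name}",
        dim_labels=spec.dim_labels(),
        peaks=peaks,
        comparable_dims=spec.comparable_dims,
        spectrum_type=spec.name,
    )


_LABEL_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z]+[0-9]*)$")


def truth_groups_from_labels(pl: PeakList) -> PeakList:
    """Recover ``truth_group`` ids from simulator-style assignment labels.

    Simulated peaks are labelled ``<aa><residue><atom>`` per dimension,
    joined by dashes (e.g. ``A45H-A45N-G44CA``); the first token names the
    anchor residue, whose index is the spin-system id.  Text peak-list
    formats keep labels but not truth ids, so this restores them after a
    round trip.  Peaks whose label does not parse are left unlabelled.
    """
    peaks = []
    for p in pl.peaks:
        tg = p.truth_group
        if tg is None and p.label:
            m = _LABEL_TOKEN.match(p.label.split("-")[0])
            if m:
                tg = int(m.group(2))
        peaks.append(Peak(p.index, p.shifts, p.label, tg))
    return PeakList(
        name=pl.name,
        dim_labels=pl.dim_labels,
        peaks=peaks,
        comparable_dims=pl.comparable_dims,
        spectrum_type=pl.spectrum_type,
    )


# ---------------------------------------------------------------------------
# Noise injection


@dataclass
class NoiseModel:
    """Per-dimension Gaussian positional noise, optionally a two-source mixture.

    ``sigmas[d]`` is the base standard deviation (ppm) for dimension ``d``.
    With ``fraction_high > 0``, ``round(fraction_high * N)`` peaks — sampled
    per peak list, per peak (both peaks of a spin system may land in
    different populations) — receive ``multiplier``-times larger noise in the
    dimensions listed in ``high_dims`` (default: all dimensions).
    """

    sigmas: tuple[float, ...]
    fraction_high: float = 0.0
    multiplier: float = 5.0
    high_dims: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigmas = tuple(float(s) for s in self.sigmas)
        if any(s < 0 for s in self.sigmas):
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.fraction_high < 1.0):
            raise ValueError("fraction_high must be in [0, 1)")


def add_noise(
    pl: PeakList,
    nm: NoiseModel,
    return_high: bool = False,
) -> PeakList | tuple[PeakList, np.ndarray]:
    """Perturb every peak position with ``N(0, sigma)`` noise per dimension.

    Labels and ``truth_group`` are preserved.  With ``return_high=True`` the
    indices of the high-variance subset are returned alongside the list.
    """
    if len(nm.sigmas) != pl.ndim:
        raise ValueError(
            f"noise model has {len(nm.sigmas)} sigmas, peak list has {pl.ndim} dims"
        )
    rng = np.random.default_rng(nm.seed)
    n = len(pl)
    high = np.zeros(n, dtype=bool)
    if nm.fraction_high > 0 and n > 0:
        n_high = int(round(nm.fraction_high * n))
        high[rng.choice(n, size=n_high, replace=False)] = True
    high_dims = set(nm.high_dims) if nm.high_dims is not None else set(range(pl.ndim))
    peaks = []
    for k, p in enumerate(pl.peaks):
        new = []
        for d, s in enumerate(p.shifts):
            sd = nm.sigmas[d]
            if high[k] and d in high_dims:
                sd *= nm.multiplier
            new.append(s + rng.normal(0.0, sd) if sd > 0 else s)
        peaks.append(Peak(k, tuple(new), p.label, p.truth_group))
    out = PeakList(
        name=pl.name,
        dim_labels=pl.dim_labels,
        peaks=peaks,
        comparable_dims=pl.comparable_dims,
        spectrum_type=pl.spectrum_type,
    )
    if return_high:
        return out, np.nonzero(high)[0]
    return out


# ---------------------------------------------------------------------------
# Filtering rules


def filter_peaklists(
    tables: Iterable[AssignedShiftTable],
    spec: SpectrumDescription,
) -> tuple[list[AssignedShiftTable], list[tuple[AssignedShiftTable, str]]]:
    """Apply the simulation-cohort filters to assigned-shift tables.

    A table is rejected when its ideal peak list contains exact duplicate
    peaks in all dimensions (such spin systems would be 100% overlapped at
    any variance), or when a residue that should contribute a CA or CB peak
    lacks that shift (other than glycine's missing CB) — a missing-data
    artefact that would depress grouping scores for the wrong reason.
    """
    kept: list[AssignedShiftTable] = []
    rejected: list[tuple[AssignedShiftTable, str]] = []
    for table in tables:
        report: list[tuple[int, str]] = []
        pl = ideal_peaklist(table, spec, missing_report=report)
        missing_cacb = sorted({(i, a) for i, a in report if a in ("CA", "CB")})
        if missing_cacb:
            detail = ", ".join(f"{a}@{i}" for i, a in missing_cacb)
            rejected.append((table, f"missing CA/CB: {detail}"))
            continue
        coords = {}
        dup = None
        for p in pl.peaks:
            if p.shifts in coords:
                dup = (coords[p.shifts], p.index)
                break
            coords[p.shifts] = p.index
        if dup is not None:
            rejected.append((table, f"duplicate peaks: {dup[0]} and {dup[1]}"))
            continue
        kept.append(table)
    return kept, rejected


# ---------------------------------------------------------------------------
# Simulation grids (noise ladders over a protein cohort)


def _dim_noise_class(spec: SpectrumDescription, d: int) -> str:
    """Noise class of a dimension: 'H', 'N' or 'C'."""
    classes = {alt.resonance_class for alt in spec.dimensions[d].expanded()}
    if classes <= {"H"}:
        return "H"
    if classes <= {"N"}:
        return "N"
    return "C"


def sigmas_for(
    spec: SpectrumDescription, sigma_h: float, sigma_c: float, sigma_n: float
) -> tuple[float, ...]:
    """Map per-nucleus-class sigmas onto a spectrum's dimensions."""
    lookup = {"H": sigma_h, "C": sigma_c, "N": sigma_n}
    return tuple(lookup[_dim_noise_class(spec, d)] for d in range(spec.ndim))


@dataclass
class SimulationGrid:
    """A ladder of noise levels applied to a cohort of proteins.

    Default ranges for the benchmark ladder: the H-dimension base
    standard deviation runs 0.001–0.050 ppm while the C and N dimensions
    run 0.01–0.50 ppm, stepped together over ``n_steps`` levels.
    ``variance_sources`` selects the regime: ``"single"`` (one source, all
    dimensions), ``"two-all"`` (20% of peaks at 5x sigma in all dimensions)
    or ``"two-n"`` (the 5x subset applies to the N dimension only).
    """

    tables: list[AssignedShiftTable]
    spectrum: str = "HNcoCACB"
    h_range: tuple[float, float] = (0.001, 0.050)
    c_range: tuple[float, float] = (0.01, 0.50)
    n_range: tuple[float, float] = (0.01, 0.50)
    n_steps: int = 50
    variance_sources: str = "single"
    fraction_high: float = 0.2
    multiplier: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance_sources not in ("single", "two-all", "two-n"):
            raise ValueError(f"unknown variance_sources {self.variance_sources!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def levels(self) -> list[tuple[float, float, float]]:
        """(sigma_H, sigma_C, sigma_N) triples for each grid step."""
        hs = np.linspace(*self.h_range, self.n_steps)
        cs = np.linspace(*self.c_range, self.n_steps)
        ns = np.linspace(*self.n_range, self.n_steps)
        return [(float(h), float(c), float(n)) for h, c, n in zip(hs, cs, ns)]

    def noise_model(
        self, spec: SpectrumDescription, level: tuple[float, float, float], seed: int
    ) -> NoiseModel:
        sigmas = sigmas_for(spec, *level)
        if self.variance_sources == "single":
            return NoiseModel(sigmas, seed=seed)
        if self.variance_sources == "two-all":
            high_dims = None
        else:  # two-n
            high_dims = tuple(
                d for d in range(spec.ndim) if _dim_noise_class(spec, d) == "N"
            )
        return NoiseModel(
            sigmas,
            fraction_high=self.fraction_high,
            multiplier=self.multiplier,
            high_dims=high_dims,
            seed=seed,
        )


def run_grid(
    grid: SimulationGrid,
    outdir: str | Path,
    format: str = "sparky",
) -> pd.DataFrame:
    """Simulate one peak-list file per (protein x noise level) and write a
    manifest CSV describing each file's condition and seed.

    Re-running with the same grid reproduces byte-identical outputs: every
    file's noise seed is derived deterministically from the grid seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = builtin_description(grid.spectrum)
    rows = []
    ext = {"sparky": "list", "autoassign": "pks", "json": "json"}[format]
    file_index = 0
    for step, level in enumerate(grid.levels()):
        for table in grid.tables:
            ideal = ideal_peaklist(table, spec)
            seed = (grid.seed * 1_000_003 + file_index) % (2**31)
            nm = grid.noise_model(spec, level, seed)
            noisy = add_noise(ideal, nm)
            fname = f"{table.protein_id}_step{step:03d}.{ext}"
            write_peaklist(noisy, outdir / fname, format=format)
            rows.append(
                {
                    "file": fname,
                    "protein_id": table.protein_id,
                    "spectrum": grid.spectrum,
                    "variance_sources": grid.variance_sources,
                    "step": step,
                    "sigma_H": level[0],
                    "sigma_C": level[1],
                    "sigma_N": level[2],
                    "fraction_high": grid.fraction_high if grid.variance_sources != "single" else 0.0,
                    "multiplier": grid.multiplier if grid.variance_sources != "single" else 1.0,
                    "n_peaks": len(noisy),
                    "seed": seed,
                }
            )
            file_index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
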