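import numpy as np
import pytest

from spingroup import (
    AssignedShiftTable,
    NoiseModel,
    Residue,
    SimulationGrid,
    add_noise,
    builtin_description,
    filter_peaklists,
    ideal_peaklist,
    read_peaklist,
    run_grid,
    synth_assignments,
    truth_groups_from_labels,
    write_peaklist,
)
from spingroup.evaluation import expected_counts
from spingroup.simulator import SHIFT_PRIORS, sigmas_for


_ATOM_OFFSET = {"H": 0.0, "N": 1.0, "CA": 2.0, "CB": 3.0, "CO": 4.0}


def table_from_seq(seq, shift=lambda aa, atom, i: 100.0 + 10 * i + _ATOM_OFFSET[atom]):
    residues = []
    for i, aa in enumerate(seq, start=1):
        shifts = {atom: float(shift(aa, atom, i)) for atom in SHIFT_PRIORS[aa]}
        residues.append(Residue(i, aa, shifts))
    return AssignedShiftTable(protein_id="toy", residues=residues)


# --- synthetic assignments -------------------------------------------------


def test_synth_assignments_deterministic():
    a = synth_assignments(40, seed=5)
    b = synth_assignments(40, seed=5)
    assert a.sequence == b.sequence
    assert all(
        ra.shifts == rb.shifts for ra, rb in zip(a.residues, b.residues)
    )


def test_synth_assignments_respects_chemistry():
    t = synth_assignments(200, seed=1)
    for r in t.residues:
        if r.aa == "G":
            assert "CB" not in r.shifts
        if r.aa == "P":
            assert "H" not in r.shifts


def test_most_synthetic_tables_pass_filters(hnco):
    tables = [synth_assignments(60, seed=s) for s in range(100)]
    kept, rejected = filter_peaklists(tables, hnco)
    assert len(kept) >= 90


# --- ideal peak list generation --------------------------------------------


def test_gaa_peptide_hand_enumeration(hnco):
    pl = ideal_peaklist(table_from_seq("GAA"), hnco)
    assert len(pl) == 3  # res2 gets CA1 only (Gly pred), res3 gets CA2+CB2
    assert sorted({p.truth_group for p in pl}) == [2, 3]
    counts = {g: sum(p.truth_group == g for p in pl) for g in (2, 3)}
    assert counts == {2: 1, 3: 2}


def test_proline_and_leading_residue_produce_no_peaks(hnco):
    pl = ideal_peaklist(table_from_seq("AAPA"), hnco)
    groups = {p.truth_group for p in pl}
    assert 1 not in groups  # no predecessor
    assert 3 not in groups  # proline lacks the amide proton
    # residue 4 follows the proline: P has CA and CB, so two peaks
    assert sum(p.truth_group == 4 for p in pl) == 2


def test_peak_count_formula_on_random_sequences(hnco):
    for seed in range(50):
        table = synth_assignments(int(60 + seed), seed=1000 + seed)
        pl = ideal_peaklist(table, hnco)
        peaks, _ = expected_counts(table.sequence, exact=True)
        assert len(pl) == peaks


def test_comparable_dims_shared_within_spin_system(hnco):
    table = synth_assignments(50, seed=9)
    pl = ideal_peaklist(table, hnco)
    by_group = {}
    for p in pl:
        by_group.setdefault(p.truth_group, []).append(p)
    for peaks in by_group.values():
        for p in peaks[1:]:
            for d in pl.comparable_dims:
                assert p.shifts[d] == peaks[0].shifts[d]


def test_ncacx_pattern(hnco):
    spec = builtin_description("NCACX")
    pl = ideal_peaklist(table_from_seq("AGA"), spec)
    # A: (N,CA,CA),(N,CA,CB),(N,CA,CO) = 3 peaks; G lacks CB = 2 peaks
    counts = {g: sum(p.truth_group == g for p in pl) for g in (1, 2, 3)}
    assert counts == {1: 3, 2: 2, 3: 3}


# --- noise -----------------------------------------------------------------


def test_zero_sigma_is_identity(hnco):
    pl = ideal_peaklist(synth_assignments(30, seed=2), hnco)
    noisy = add_noise(pl, NoiseModel((0.0, 0.0, 0.0), seed=4))
    assert all(a.shifts == b.shifts for a, b in zip(pl, noisy))


def test_noise_statistics_match_sigma(hnco):
    pl = ideal_peaklist(synth_assignments(100, seed=3), hnco)
    reps = []
    for seed in range(60):
        noisy = add_noise(pl, NoiseModel((0.01, 0.1, 0.1), seed=seed))
        reps.extend(
            n.shifts[0] - p.shifts[0] for p, n in zip(pl, noisy)
        )
    reps = np.array(reps)  # > 10000 perturbations
    assert len(reps) >= 10000
    assert abs(reps.std() / 0.01 - 1) < 0.02
    assert abs(reps.mean()) < 3 * 0.01 / np.sqrt(len(reps))


def test_mixture_flags_exact_fraction(hnco):
    table = synth_assignments(56, seed=8)
    pl = ideal_peaklist(table, hnco)
    n = len(pl)
    nm = NoiseModel((0.01, 0.1, 0.1), fraction_high=0.2, multiplier=5, seed=3)
    noisy, high = add_noise(pl, nm, return_high=True)
    assert len(high) == round(0.2 * n)
    assert len(noisy) == n
    assert [p.truth_group for p in noisy] == [p.truth_group for p in pl]


def test_mixture_std_matches_theory(hnco):
    pl = ideal_peaklist(synth_assignments(100, seed=3), hnco)
    sigma = 0.01
    diffs = []
    for seed in range(20):
        nm = NoiseModel((sigma, 10 * sigma, 10 * sigma), fraction_high=0.2,
                        multiplier=5, seed=seed)
        noisy = add_noise(pl, nm)
        diffs.extend(n.shifts[0] - p.shifts[0] for p, n in zip(pl, noisy))
    theory = sigma * np.sqrt(0.8 + 0.2 * 25)
    assert len(diffs) >= 2000
    assert abs(np.std(diffs) / theory - 1) < 0.05


# --- filters ---------------------------------------------------------------


def test_duplicate_peaks_rejected(hnco):
    # two residues with identical amide and identical predecessor carbons
    def shift(aa, atom, i):
        return {"H": 8.0, "N": 118.0, "CA": 55.0, "CB": 30.0, "CO": 176.0}[atom]

    table = table_from_seq("AAAA", shift)
    kept, rejected = filter_peaklists([table], hnco)
    assert not kept
    assert "duplicate peaks" in rejected[0][1]


def test_missing_cb_rejected(hnco):
    table = table_from_seq("AAA")
    del table.residues[1].shifts["CB"]  # alanine missing CB
    kept, rejected = filter_peaklists([table], hnco)
    assert not kept
    assert "missing CA/CB" in rejected[0][1]


def test_clean_table_kept(hnco):
    kept, rejected = filter_peaklists([synth_assignments(30, seed=17)], hnco)
    assert len(kept) == 1 and not rejected


# --- grids -----------------------------------------------------------------


def test_toy_grid_files_and_manifest(tmp_path):
    tables = [synth_assignments(20, seed=s) for s in (1, 2)]
    grid = SimulationGrid(tables=tables, n_steps=3, seed=5)
    manifest = run_grid(grid, tmp_path / "sims")
    assert len(manifest) == 6
    assert (tmp_path / "sims" / "manifest.csv").exists()
    for fname in manifest["file"]:
        assert (tmp_path / "sims" / fname).exists()
    assert manifest["seed"].nunique() == 6


def test_grid_rerun_is_byte_identical(tmp_path):
    tables = [synth_assignments(20, seed=3)]
    grid = SimulationGrid(tables=tables, n_steps=2, seed=9)
    m1 = run_grid(grid, tmp_path / "a")
    m2 = run_grid(grid, tmp_path / "b")
    for fname in m1["file"]:
        assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()


def test_grid_default_ranges_cover_benchmark_ladder():
    grid = SimulationGrid(tables=[])
    levels = grid.levels()
    assert len(levels) == 50
    assert levels[0] == pytest.approx((0.001, 0.01, 0.01))
    assert levels[-1] == pytest.approx((0.050, 0.50, 0.50))


def test_truth_labels_survive_text_round_trip(tmp_path, hnco):
    pl = ideal_peaklist(synth_assignments(30, seed=21), hnco)
    path = tmp_path / "x.list"
    write_peaklist(pl, path, format="sparky")
    back = truth_groups_from_labels(read_peaklist(path, format="sparky"))
    assert back.truth_groups() == pl.truth_groups()


def test_sigmas_for_maps_nucleus_classes(hnco):
    assert sigmas_for(hnco, 0.001, 0.3, 0.04) == (0.001, 0.04, 0.3)
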