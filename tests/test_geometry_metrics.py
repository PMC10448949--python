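import numpy as np
import pytest

from modefit.geometry_metrics import (
    CapriMetrics,
    MetricError,
    capri_class,
    conformational_difference,
    define_interface,
    evaluate_model,
    f_nat,
    i_rmsd,
    kabsch,
    l_rmsd,
    native_contacts,
    pair_residues,
)
from modefit.fixtures import HingeSpec, make_two_domain_protein, make_bound_state

from conftest import make_residue, single_atom_structure


# ---------------------------------------------------------------------------
# superposition


def quaternion_rmsd(P, Q):
    """Independent quaternion-based minimum RMSD (Horn's method)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P**2) + np.sum(Q**2) - 2 * lam) / len(P)
    return np.sqrt(max(msd, 0.0))


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def test_kabsch_identity():
    P = np.random.default_rng(0).normal(size=(10, 3))
    sup = kabsch(P, P)
    assert sup.rmsd < 1e-12
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)


def test_kabsch_recovers_random_rigid_transform(rng):
    P = rng.normal(size=(12, 3)) * 5
    R = random_rotation(rng)
    t = rng.normal(size=3) * 10
    Q = P @ R.T + t
    sup = kabsch(P, Q)
    assert sup.rmsd < 1e-8
    np.testing.assert_allclose(sup.rotation, R, atol=1e-8)
    np.testing.assert_allclose(sup.translation, t, atol=1e-8)
    assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-6


@pytest.mark.parametrize("n", [4, 10, 50])
def test_kabsch_matches_quaternion_oracle(n, rng):
    P = rng.normal(size=(n, 3)) * 3
    Q = rng.normal(size=(n, 3)) * 3
    assert kabsch(P, Q).rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-8)


def test_kabsch_rejects_degenerate_input():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(MetricError):
        kabsch(line, line + 1.0)
    with pytest.raises(MetricError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# residue pairing


def protein_chain(seq, chain_id="A"):
    from modefit.structure_io import Residue, Atom

    one_to_three = {"A": "ALA", "G": "GLY", "L": "LEU", "K": "LYS", "V": "VAL",
                    "F": "PHE", "S": "SER", "T": "THR", "D": "ASP", "E": "GLU"}
    return [
        make_residue(chain_id, i + 1, one_to_three[c],
                     [("CA", "C", [i * 3.8, 0, 0])], "protein")
        for i, c in enumerate(seq)
    ]


def test_pair_identical_sequences_full_coverage():
    a = protein_chain("AGLKVFSTDE")
    b = protein_chain("AGLKVFSTDE", chain_id="B")
    p = pair_residues(a, b)
    assert len(p.pairs) == 10
    assert p.coverage == 1.0
    assert all(ra.seq_num == rb.seq_num for ra, rb in p.pairs)


def test_pair_with_deletion_excludes_missing_block():
    seq = "AGLKVFSTDE" * 2
    a = protein_chain(seq)
    b = protein_chain(seq[:8] + seq[13:], chain_id="B")  # drop 5 middle residues
    p = pair_residues(a, b)
    paired_a = {ra.seq_num for ra, _ in p.pairs}
    assert paired_a == set(range(1, 21)) - {9, 10, 11, 12, 13}


def test_pair_protein_vs_rna_raises():
    a = protein_chain("AGLKV")
    b = [make_residue("B", i + 1, "A", [("P", "P", [i * 6.0, 0, 0])], "rna")
         for i in range(5)]
    with pytest.raises(MetricError, match="both must be protein or both nucleic"):
        pair_residues(a, b)


def test_conformational_difference_zero_on_self():
    s, _ = make_two_domain_protein(HingeSpec(seed=2))
    assert conformational_difference(s, s) == pytest.approx(0.0, abs=1e-9)


def test_conformational_difference_matches_bruteforce_kabsch():
    """The hinge fixture's unbound-vs-bound Cα RMSD equals a direct Kabsch on
    the CA arrays (residues correspond 1:1 by construction)."""
    spec = HingeSpec(seed=2)
    s, domains = make_two_domain_protein(spec)
    b = make_bound_state(s, domains, spec)
    P = np.array([r.atom("CA").pos for r in s.residues()])
    Q = np.array([r.atom("CA").pos for r in b.residues()])
    assert conformational_difference(s, b) == pytest.approx(
        kabsch(P, Q).rmsd, abs=1e-9
    )


# ---------------------------------------------------------------------------
# interface / contacts / CAPRI metrics


def test_interface_cutoff_boundary():
    rec = single_atom_structure("R", [[0.0, 0, 0]])
    lig_in = single_atom_structure("L", [[9.9, 0, 0]])
    lig_out = single_atom_structure("L", [[10.1, 0, 0]])
    inside = define_interface(rec, lig_in)
    assert len(inside.receptor_residues) == 1 and len(inside.ligand_residues) == 1
    outside = define_interface(rec, lig_out)
    assert not outside.receptor_residues and not outside.ligand_residues


def brute_force_pairs(rec, lig, cutoff):
    out = set()
    for rr in rec.residues():
        for lr in lig.residues():
            for a in rr.atoms:
                for b in lr.atoms:
                    if np.linalg.norm(a.pos - b.pos) <= cutoff:
                        out.add((rr.key, lr.key))
    return out


def test_interface_and_contacts_match_bruteforce(rng):
    rec = single_atom_structure("R", rng.uniform(0, 15, size=(6, 3)))
    lig = single_atom_structure("L", rng.uniform(5, 20, size=(6, 3)))
    iface = define_interface(rec, lig)
    expected = brute_force_pairs(rec, lig, 10.0)
    assert iface.receptor_residues == frozenset(r for r, _ in expected)
    assert iface.ligand_residues == frozenset(l for _, l in expected)
    contacts = native_contacts(rec, lig)
    assert contacts.contacts == frozenset(brute_force_pairs(rec, lig, 5.0))


def test_f_nat_enumerated_fraction():
    """3 native contacts; a model keeping exactly one scores 1/3."""
    rec = single_atom_structure("R", [[0, 0, 0], [20, 0, 0], [40, 0, 0]])
    lig = single_atom_structure("L", [[3, 0, 0], [23, 0, 0], [43, 0, 0]])
    nat = native_contacts(rec, lig)
    assert len(nat.contacts) == 3
    model_lig = single_atom_structure("L", [[3, 0, 0], [23, 9, 0], [43, 9, 0]])
    assert f_nat(nat, rec, model_lig) == pytest.approx(1 / 3)
    assert f_nat(nat, rec, lig) == 1.0
    far = single_atom_structure("L", [[103, 0, 0], [123, 0, 0], [143, 0, 0]])
    assert f_nat(nat, rec, far) == 0.0


def test_f_nat_empty_native_set_is_error():
    rec = single_atom_structure("R", [[0, 0, 0]])
    lig = single_atom_structure("L", [[50, 0, 0]])
    with pytest.raises(MetricError, match="empty"):
        f_nat(native_contacts(rec, lig), rec, lig)


def _hinge_complex_parts(hinge):
    unbound, bound, receptor, domains = hinge
    return receptor, bound


def test_irmsd_zero_for_native(hinge):
    receptor, bound = _hinge_complex_parts(hinge)
    assert i_rmsd(receptor, bound, receptor, bound) == pytest.approx(0.0, abs=1e-9)
    assert l_rmsd(receptor, bound, receptor, bound) == pytest.approx(0.0, abs=1e-9)


def test_lrmsd_pure_translation(hinge):
    """A 7 Å rigid ligand translation with receptor fixed gives exactly 7.0."""
    receptor, bound = _hinge_complex_parts(hinge)
    moved = bound.copy()
    moved.set_coords(bound.coords() + np.array([7.0, 0.0, 0.0]))
    assert l_rmsd(receptor, bound, receptor, moved) == pytest.approx(7.0, abs=1e-9)


def test_irmsd_matches_direct_recomputation(hinge):
    """Rotating the ligand 10° about an interface axis: I-RMSD equals an
    independent Kabsch on the interface backbone atoms."""
    from modefit.geometry_metrics import PROTEIN_BACKBONE, NUCLEIC_BACKBONE

    receptor, bound = _hinge_complex_parts(hinge)
    t = np.radians(10.0)
    R = np.array([
        [np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]
    ])
    pivot = bound.coords().mean(axis=0)
    moved = bound.copy()
    moved.set_coords((bound.coords() - pivot) @ R.T + pivot)
    iface = define_interface(receptor, bound)
    P, Q = [], []
    for native_s, model_s, keys in (
        (receptor, receptor, iface.receptor_residues),
        (bound, moved, iface.ligand_residues),
    ):
        model_res = {r.key: r for r in model_s.residues()}
        for res in native_s.residues():
            if res.key not in keys:
                continue
            names = PROTEIN_BACKBONE if res.polymer_type == "protein" else NUCLEIC_BACKBONE
            for nm in names:
                a, b = res.atom(nm), model_res[res.key].atom(nm)
                if a is not None and b is not None:
                    P.append(a.pos)
                    Q.append(b.pos)
    expected = kabsch(np.array(P), np.array(Q)).rmsd
    assert i_rmsd(receptor, bound, receptor, moved) == pytest.approx(expected, abs=1e-9)


def test_metrics_invariant_under_global_rigid_motion(hinge, rng):
    """Applying one rigid transform to the whole model complex leaves
    f_nat/I-RMSD/L-RMSD unchanged within 1e-6."""
    receptor, bound = _hinge_complex_parts(hinge)
    moved_lig = bound.copy()
    moved_lig.set_coords(bound.coords() + np.array([2.0, -1.0, 0.5]))
    base = evaluate_model(receptor, bound, receptor, moved_lig)
    R = random_rotation(rng)
    t = rng.normal(size=3) * 20
    rec2, lig2 = receptor.copy(), moved_lig.copy()
    rec2.set_coords(receptor.coords() @ R.T + t)
    lig2.set_coords(moved_lig.coords() @ R.T + t)
    after = evaluate_model(receptor, bound, rec2, lig2)
    assert after.f_nat == pytest.approx(base.f_nat, abs=1e-9)
    assert after.i_rmsd == pytest.approx(base.i_rmsd, abs=1e-6)
    assert after.l_rmsd == pytest.approx(base.l_rmsd, abs=1e-6)


def test_f_nat_monotone_under_separation(hinge):
    receptor, bound = _hinge_complex_parts(hinge)
    nat = native_contacts(receptor, bound)
    values = []
    for shift in [0.0, 2.0, 5.0, 12.0, 40.0]:
        moved = bound.copy()
        moved.set_coords(bound.coords() + np.array([0.0, shift, 0.0]))
        values.append(f_nat(nat, receptor, moved))
    assert values[0] == 1.0
    assert all(a >= b for a, b in zip(values, values[1:]))


@pytest.mark.parametrize(
    "fn,ir,lr,expected",
    [
        # published case-study triples: an acceptable model via the L-RMSD
        # branch, an incorrect one failing the f_nat floor, and a perfect model
        (0.26, 6.9, 5.5, "acceptable_or_better"),
        (0.03, 10.9, 9.5, "incorrect"),
        (1.0, 0.0, 0.0, "acceptable_or_better"),
        (0.40, 4.6, 8.7, "acceptable_or_better"),
        (0.12, 4.5, 10.5, "incorrect"),
    ],
)
def test_capri_classification_rule(fn, ir, lr, expected):
    assert capri_class(CapriMetrics(f_nat=fn, i_rmsd=ir, l_rmsd=lr)) == expected


def test_capri_rejects_nonfinite():
    with pytest.raises(MetricError):
        capri_class(CapriMetrics(f_nat=np.nan, i_rmsd=1.0, l_rmsd=1.0))
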