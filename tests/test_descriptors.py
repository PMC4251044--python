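import numpy as np
import pytest

from seqsubtype import descriptors as d
from seqsubtype.errors import LengthError
from seqsubtype.sequence_io import STANDARD_RESIDUES, ProteinRecord

from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles (naive direct summation / scanning)


def naive_moran(p, dmax):
    p = np.asarray(p, float)
    n = len(p)
    pbar = p.mean()
    den = sum((x - pbar) ** 2 for x in p) / n
    out = []
    for lag in range(1, dmax + 1):
        if den == 0:
            out.append(0.0)
            continue
        num = sum((p[j] - pbar) * (p[j + lag] - pbar) for j in range(n - lag)) / (n - lag)
        out.append(num / den)
    return np.array(out)


def naive_geary(p, dmax):
    p = np.asarray(p, float)
    n = len(p)
    pbar = p.mean()
    den = sum((x - pbar) ** 2 for x in p) / (n - 1)
    out = []
    for lag in range(1, dmax + 1):
        if den == 0:
            out.append(0.0)
            continue
        num = sum((p[j] - p[j + lag]) ** 2 for j in range(n - lag)) / (2 * (n - lag))
        out.append(num / den)
    return np.array(out)


def naive_mba(p, dmax, normalized=True):
    p = np.asarray(p, float)
    n = len(p)
    out = []
    for lag in range(1, dmax + 1):
        s = sum(p[j] * p[j + lag] for j in range(n - lag))
        out.append(s / (n - lag) if normalized else s)
    return np.array(out)


def scan_pi(seq, pka):
    """Brute-force net-charge zero crossing on a fine pH grid."""
    phs = np.arange(0.0, 14.0, 5e-4)
    pos = 1 / (1 + 10 ** (phs - pka["n_term"]))
    for aa in "KRH":
        pos = pos + seq.count(aa) / (1 + 10 ** (phs - pka[aa]))
    neg = 1 / (1 + 10 ** (pka["c_term"] - phs))
    for aa in "DECY":
        neg = neg + seq.count(aa) / (1 + 10 ** (pka[aa] - phs))
    return phs[np.argmin(np.abs(pos - neg))]


# ---------------------------------------------------------------------------


class TestCompositionDescriptors:
    def test_aac_homopolymer(self):
        v = d.aac(make_record("AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_aac_all_residues_uniform(self):
        v = d.aac(make_record(STANDARD_RESIDUES))
        assert np.allclose(v, 0.05)

    def test_aac_direct_count(self):
        v = d.aac(make_record("AAC"))
        assert v[STANDARD_RESIDUES.index("A")] == pytest.approx(2 / 3)
        assert v[STANDARD_RESIDUES.index("C")] == pytest.approx(1 / 3)

    def test_dipep_examples(self):
        v = d.dipep(make_record("AAAA"))
        assert v[0] == 1.0 and v.sum() == 1.0
        v = d.dipep(make_record("ACA"))
        ia, ic = STANDARD_RESIDUES.index("A"), STANDARD_RESIDUES.index("C")
        assert v[ia * 20 + ic] == 0.5 and v[ic * 20 + ia] == 0.5

    def test_dipep_sums_to_one_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=50))
        assert d.dipep(make_record(seq)).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seq", ["AAA", "GVA"])
    def test_conjoint_triad_group_collapse(self, seq):
        v = d.conjoint_triad(make_record(seq))
        assert v[0] == 1.0  # triad (g1, g1, g1)

    def test_conjoint_triad_mixed_groups(self):
        # A -> group 1, R -> group 5, C -> group 7
        v = d.conjoint_triad(make_record("ARC"))
        assert v[0 * 49 + 4 * 7 + 6] == 1.0

    @pytest.mark.parametrize(
        "fn,min_len",
        [(d.dipep, 2), (d.conjoint_triad, 3), (d.ctd, 2), (d.saac, 51)],
    )
    def test_length_preconditions(self, fn, min_len):
        with pytest.raises(LengthError):
            fn(make_record("A" * (min_len - 1)))


class TestCTD:
    def test_homopolymer_distribution(self):
        v = d.ctd(make_record("A" * 10))
        assert v[0] == 1.0  # composition of group 1
        assert np.all(v[7:28] == 0.0)  # no transitions
        assert np.allclose(v[28:33], [10, 30, 50, 80, 100])
        assert np.all(v[33:] == 0.0)  # absent groups

    def test_composition_block_is_partition(self, random_records):
        for r in random_records[:10]:
            assert d.ctd(r)[:7].sum() == pytest.approx(1.0, abs=1e-9)

    def test_adjacent_group_transition(self):
        # A in group 1, D in group 6 -> pair {g1, g6} is the 5th of 21 pairs
        v = d.ctd(make_record("AD"))
        assert v[7 + 4] == 1.0


class TestAutocorrelation:
    def test_matches_naive_oracles(self, random_records):
        props = d.default_properties()
        for r in random_records[:8]:
            for enc, oracle in [
                (d.moran, naive_moran),
                (d.geary, naive_geary),
                (d.moreau_broto, naive_mba),
            ]:
                got = enc(r, props, max_lag=30)
                for pi, name in enumerate(props.names):
                    p = props.profile(name, r.sequence)
                    np.testing.assert_allclose(
                        got[pi * 30 : (pi + 1) * 30], oracle(p, 30), atol=1e-9
                    )

    def test_constant_property_gives_zero(self):
        props = d.PropertySet({"flat": {aa: 3.0 for aa in STANDARD_RESIDUES}}, normalize=False)
        r = make_record("ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY")
        assert np.all(d.moran(r, props, max_lag=5) == 0.0)
        assert np.all(d.geary(r, props, max_lag=5) == 0.0)

    def test_toy_scale_hand_values(self):
        scale = {aa: 0.0 for aa in STANDARD_RESIDUES}
        scale.update({"A": 1.0, "C": -2.0})
        props = d.PropertySet({"toy": scale}, normalize=False)
        # "ACA": p = (1, -2, 1); pbar = 0; moran d=1: mean(p0*p1, p1*p2)/mean(p^2)
        got = d.moran(make_record("ACA"), props, max_lag=1)
        assert got[0] == pytest.approx(((1 * -2) + (-2 * 1)) / 2 / ((1 + 4 + 1) / 3))
        got = d.geary(make_record("ACA"), props, max_lag=1)
        assert got[0] == pytest.approx(((3**2) + (3**2)) / 4 / ((1 + 4 + 1) / 2))
        got = d.moreau_broto(make_record("AAC"), props, max_lag=1)
        assert got[0] == pytest.approx(((1 * 1) + (1 * -2)) / 2)

    def test_raw_moreau_broto_flag(self):
        props = d.default_properties()
        r = make_record("ACDEFGHIKLMNPQRSTVWY" * 2)
        raw = d.moreau_broto(r, props, max_lag=5, normalize_by_length=False)
        norm = d.moreau_broto(r, props, max_lag=5)
        n = len(r.sequence)
        divisors = np.tile(n - np.arange(1, 6), len(props.names))
        np.testing.assert_allclose(norm, raw / divisors, atol=1e-12)

    def test_too_short_sequence_names_minimum(self):
        with pytest.raises(LengthError, match="31"):
            d.moran(make_record("ACDE"), max_lag=30)


class TestPhysicochemical:
    def test_acidic_homopolymer_class_fractions(self):
        v = d.physicochemical(make_record("D" * 10))
        names = d.PHYSCHEM_FEATURE_NAMES
        get = lambda n: v[names.index(n)]
        assert get("charged") == 1.0
        assert get("acidic") == 1.0
        assert get("acidic_amide") == 1.0
        assert get("ionizable") == 1.0
        assert get("aliphatic") == 0.0
        assert get("aromatic") == 0.0
        assert get("cyclic") == 0.0

    def test_scaled_mw_and_length_elements(self, random_records):
        names = d.PHYSCHEM_FEATURE_NAMES
        for r in random_records[:5]:
            v = d.physicochemical(r)
            assert v[names.index("length_scaled")] == pytest.approx(len(r) / 38000.0)
            assert v[names.index("mw_scaled")] == pytest.approx(d.molecular_weight(r) / 4e6)
            assert np.all((v > 0) | (v == 0)) and np.all(v <= 1.0)

    def test_pi_element_matches_bisection_oracle(self):
        r = make_record("D" * 10)
        v = d.physicochemical(r)
        oracle = scan_pi(r.sequence, d.PKA)
        assert v[d.PHYSCHEM_FEATURE_NAMES.index("pI")] == pytest.approx(oracle / 14.0, abs=1e-3)
        assert oracle < 7.0  # acidic homopolymer

    def test_molecular_weight_glycine(self):
        assert d.molecular_weight(make_record("G")) == pytest.approx(75.07, abs=0.01)

    def test_molecular_weight_additivity(self):
        delta = d.molecular_weight(make_record("AA")) - d.molecular_weight(make_record("A"))
        assert delta == pytest.approx(71.079, abs=0.001)

    def test_molecular_weight_against_biopython(self, random_records):
        from Bio.SeqUtils import molecular_weight as bio_mw

        for r in random_records[:5]:
            assert d.molecular_weight(r) == pytest.approx(
                bio_mw(r.sequence, seq_type="protein"), rel=1e-4
            )


class TestIsoelectricPoint:
    def test_returned_ph_has_near_zero_charge(self, random_records):
        for r in random_records[:10]:
            ph = d.isoelectric_point(r)
            assert abs(d._net_charge(r.sequence, ph)) < 1e-4

    def test_basic_homopolymer(self):
        assert d.isoelectric_point(make_record("K" * 10)) > 9.0

    def test_acidic_homopolymer(self):
        assert d.isoelectric_point(make_record("D" * 10)) < 5.0

    def test_matches_grid_scan(self, random_records):
        for r in random_records[:5]:
            assert d.isoelectric_point(r) == pytest.approx(
                scan_pi(r.sequence, d.PKA), abs=1e-3
            )


class TestSplitComposition:
    def test_homopolymer_blocks(self):
        v = d.saac(make_record("A" * 75))
        ia = STANDARD_RESIDUES.index("A")
        for block in range(3):
            assert v[block * 20 + ia] == 1.0

    def test_blocks_sum_to_one(self, random_records):
        for r in random_records[:5]:
            if len(r) >= 51:
                v = d.saac(r)
                for block in range(3):
                    assert v[block * 20 : (block + 1) * 20].sum() == pytest.approx(1.0)

    def test_minimum_length_center_is_single_residue(self):
        seq = "A" * 25 + "W" + "A" * 25
        v = d.saac(make_record(seq))
        iw = STANDARD_RESIDUES.index("W")
        assert v[20 + iw] == 1.0  # center block is exactly the W


class TestEncodeDispatch:
    @pytest.mark.parametrize("name,dim", sorted(d.DESCRIPTOR_DIMS.items()))
    def test_dimensions(self, name, dim, random_records):
        m = d.encode(random_records[:3], name)
        assert m.shape == (3, dim)
        assert len(m.feature_names) == dim

    def test_composite_is_concatenation(self, random_records):
        r = random_records[0]
        v = d.composite_aac_physchem(r)
        np.testing.assert_array_equal(v[:20], d.aac(r))
        np.testing.assert_array_equal(v[20:], d.physicochemical(r))

    def test_descriptors_depend_only_on_sequence(self, random_records):
        r = random_records[0]
        r2 = ProteinRecord(id="other", sequence=r.sequence, description="changed")
        for name in d.DESCRIPTOR_NAMES:
            a = d.encode([r], name).values
            b = d.encode([r2], name).values
            np.testing.assert_array_equal(a, b)

    def test_tsv_roundtrip(self, tmp_path, random_records):
        m = d.encode(random_records[:4], "physchem")
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = d.FeatureMatrix.from_tsv(p, "physchem")
        assert back.row_ids == m.row_ids
        assert back.feature_names == m.feature_names
        np.testing.assert_allclose(back.values, m.values, atol=1e-12)
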