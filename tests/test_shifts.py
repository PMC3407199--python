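"""Random-coil referencing, secondary shifts, CSI and Karplus inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpnmr import (
    PeptideSequence,
    RandomCoilTable,
    ShiftRecord,
    consensus_csi,
    corrected_random_coil,
    flag_deviant,
    karplus_j,
    karplus_phi,
    load_coil_table,
    secondary_shifts,
)


@pytest.fixture(scope="module")
def coil():
    return load_coil_table("urea8m")


class TestCorrectedRandomCoil:
    def test_no_corrections_returns_base(self, coil):
        seq = PeptideSequence("NLYIQ")
        bare = RandomCoilTable(coil.base, {}, coil.provenance)
        ref = corrected_random_coil(seq, bare)
        assert ref[(1, "CA")] == coil.base[("N", "CA")]
        assert ref[(5, "C")] == coil.base[("Q", "C")]

    def test_single_residue_has_no_neighbour_terms(self, coil):
        ref = corrected_random_coil(PeptideSequence("W"), coil)
        assert ref[(1, "CA")] == coil.base[("W", "CA")]

    def test_synthetic_corrections_match_hand_sum(self):
        """Gly-rich word with hand-built increments at every offset."""
        seq = PeptideSequence("GAGWG")
        base = {(aa, "CA"): 50.0 for aa in "GAW"}
        corr = {
            ("G", -2, "CA"): 0.11, ("G", -1, "CA"): 0.23,
            ("G", 1, "CA"): 0.37, ("G", 2, "CA"): 0.41,
            ("W", 1, "CA"): -1.0,
        }
        table = RandomCoilTable(base, corr, "synthetic")
        ref = corrected_random_coil(seq, table, nuclei=["CA"])
        # residue 3 (G): neighbours G at -2, A at -1, W at +1, G at +2
        assert ref[(3, "CA")] == pytest.approx(50.0 + 0.11 - 1.0 + 0.41)
        # residue 1 (G): only +1 (A) and +2 (G) exist
        assert ref[(1, "CA")] == pytest.approx(50.0 + 0.41)
        # residue 5 (G): only -1 (W) and -2 (G) neighbours
        assert ref[(5, "CA")] == pytest.approx(50.0 + 0.11)

    def test_preceding_proline_correction_applied(self, coil):
        seq = PeptideSequence("GP")
        ref = corrected_random_coil(seq, coil, nuclei=["CA"])
        assert ref[(1, "CA")] == pytest.approx(coil.base[("G", "CA")] - 2.0)

    def test_missing_residue_type_reported(self):
        table = RandomCoilTable({("A", "CA"): 50.0}, {}, "partial")
        with pytest.raises(KeyError, match="'G'"):
            corrected_random_coil(PeptideSequence("AG"), table, nuclei=["CA"])


class TestSecondaryShifts:
    def test_zero_everywhere_when_observed_equals_reference(self, coil, tc5b):
        ref = corrected_random_coil(tc5b, coil)
        obs = [ShiftRecord(r, n, v) for (r, n), v in ref.items()]
        recs = secondary_shifts(obs, ref)
        assert all(r.ddelta == 0.0 for r in recs)

    def test_asp_excluded_regardless_of_ddelta(self, coil, tc5b):
        ref = corrected_random_coil(tc5b, coil)
        obs = [ShiftRecord(9, "CA", ref[(9, "CA")] + 5.0)]
        recs = secondary_shifts(obs, ref, tc5b, exclude_ph_sensitive=True)
        assert recs[0].excluded and "pH" in recs[0].exclusion_reason

    def test_localized_perturbation_recovered_exactly(self, coil, tc5b):
        ref = corrected_random_coil(tc5b, coil)
        obs = []
        for (r, n), v in ref.items():
            bump = 0.5 if (n == "CA" and 4 <= r <= 7) else 0.0
            obs.append(ShiftRecord(r, n, v + bump))
        recs = secondary_shifts(obs, ref)
        hot = {r.residue for r in recs if r.ddelta != 0.0}
        assert hot == {4, 5, 6, 7}
        assert all(r.ddelta == pytest.approx(0.5) for r in recs
                   if r.residue in hot and r.nucleus == "CA")

    def test_antisymmetry_under_swapping(self, coil, tc5b):
        ref = corrected_random_coil(tc5b, coil)
        rng = np.random.default_rng(0)
        obs = [ShiftRecord(r, n, v + rng.normal(0, 0.3))
               for (r, n), v in ref.items()]
        fwd = secondary_shifts(obs, ref)
        swapped_ref = {(r.residue, r.nucleus): r.shift_ppm for r in obs}
        swapped_obs = [ShiftRecord(r, n, v) for (r, n), v in ref.items()]
        rev = secondary_shifts(swapped_obs, swapped_ref)
        for a, b in zip(fwd, rev):
            assert b.ddelta == pytest.approx(-a.ddelta)


class TestConsensusCsi:
    @staticmethod
    def _records(dd):
        """dd: {(residue, nucleus): ddelta}."""
        from idpnmr import SecondaryShiftRecord

        return [SecondaryShiftRecord(r, n, v, 0.0, v) for (r, n), v in dd.items()]

    def test_all_zero_gives_all_coil(self):
        dd = {(r, n): 0.0 for r in range(1, 21) for n in ("CA", "CB", "C")}
        result = consensus_csi(self._records(dd))
        assert set(result.consensus.values()) == {"coil"}

    def test_synthetic_helix_block(self):
        dd = {}
        for r in range(1, 21):
            helix = 3 <= r <= 9
            dd[(r, "CA")] = 0.8 if helix else 0.0
            dd[(r, "C")] = 0.8 if helix else 0.0
            dd[(r, "CB")] = -0.8 if helix else 0.0
        result = consensus_csi(self._records(dd))
        for r in range(1, 21):
            expected = "helix" if 3 <= r <= 9 else "coil"
            assert result.consensus[r] == expected, r

    def test_short_run_suppressed(self):
        dd = {(r, n): 0.0 for r in range(1, 21) for n in ("CA", "CB", "C")}
        dd[(10, "CA")] = 1.5  # single-residue exceedance
        result = consensus_csi(self._records(dd))
        assert result.consensus[10] == "coil"
        assert result.indices[(10, "CA")] == 1

    def test_invariant_to_uniform_referencing_offset(self):
        rng = np.random.default_rng(4)
        dd = {(r, n): float(rng.normal(0, 0.6))
              for r in range(1, 21) for n in ("CA", "CB", "C")}
        base = consensus_csi(self._records(dd))
        from idpnmr import SecondaryShiftRecord

        offset_recs = [
            SecondaryShiftRecord(r, n, v + 3.0, 3.0, v) for (r, n), v in dd.items()
        ]
        shifted = consensus_csi(offset_recs)
        assert shifted.consensus == base.consensus

    def test_strand_call_from_inverted_signs(self):
        dd = {}
        for r in range(1, 11):
            strand = 4 <= r <= 8
            dd[(r, "CA")] = -0.9 if strand else 0.0
            dd[(r, "C")] = -0.9 if strand else 0.0
            dd[(r, "CB")] = 0.9 if strand else 0.0
        result = consensus_csi(self._records(dd))
        assert result.consensus[5] == "strand"


class TestFlagDeviant:
    @staticmethod
    def _records(dd, excluded=()):
        from idpnmr import SecondaryShiftRecord

        out = []
        for (r, n), v in dd.items():
            rec = SecondaryShiftRecord(r, n, v, 0.0, v)
            rec.excluded = r in excluded
            out.append(rec)
        return out

    def test_threshold_above_max_flags_nothing(self):
        dd = {(r, "CA"): 0.2 for r in range(1, 6)}
        assert flag_deviant(self._records(dd), {"CA": 0.5}) == []

    def test_constructed_exceedances_flagged_exactly(self):
        """CA deviants at 4, 7, 12, 18 only — the pattern of a localized
        hydrophobic cluster read out through CA shifts."""
        dd = {(r, "CA"): (0.6 if r in (4, 7, 12, 18) else 0.1)
              for r in range(1, 21)}
        flagged = flag_deviant(self._records(dd), {"CA": 0.3})
        assert sorted(f.residue for f in flagged) == [4, 7, 12, 18]

    def test_excluded_records_never_flagged(self):
        dd = {(9, "CA"): 5.0}
        assert flag_deviant(self._records(dd, excluded={9}), {"CA": 0.3}) == []

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lo=st.floats(0.05, 1.0),
        extra=st.floats(0.01, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_monotone_in_threshold(self, lo, extra, seed):
        rng = np.random.default_rng(seed)
        dd = {(r, "CA"): float(rng.normal(0, 0.5)) for r in range(1, 21)}
        small = {f.residue for f in flag_deviant(self._records(dd), {"CA": lo})}
        large = {f.residue for f in flag_deviant(self._records(dd),
                                                 {"CA": lo + extra})}
        assert large <= small


class TestKarplus:
    def test_theta_zero_identity(self):
        a, b, c = 6.51, -1.76, 1.60
        est = karplus_phi(a + b + c)
        assert any(abs(s - 60.0) < 1e-6 for s in est.solutions)

    def test_above_curve_maximum_has_no_solutions(self):
        assert karplus_phi(50.0).solutions == []

    def test_every_solution_satisfies_curve_to_001_hz(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            j = rng.uniform(0.0, 9.5)
            for phi in karplus_phi(j).solutions:
                assert abs(karplus_j(phi) - j) < 0.01

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            phi = rng.uniform(-180.0, 180.0)
            est = karplus_phi(karplus_j(phi))
            assert any(
                abs(((s - phi + 180) % 360) - 180) < 0.1 for s in est.solutions
            ), phi

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            karplus_phi(-1.0)
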