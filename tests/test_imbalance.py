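import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umprofiler.imbalance import (
    BandConfig,
    ImbalanceStatus,
    SnpObservation,
    ZygosityBand,
    band_snp,
    call_chromosome,
    call_patient_imbalances,
)
from umprofiler.panel_model import SnpLocus


def obs(vaf_pct, chrom="3", arm="p", patient="P1", depth=500, rsid=None, idx=[0]):
    idx[0] += 1
    alt = round(vaf_pct / 100 * depth)
    return SnpObservation(
        patient_id=patient,
        locus=SnpLocus(rsid or f"rs{idx[0]}", chrom, arm, 1000 + idx[0]),
        total_depth=depth,
        alt_depth=alt,
    )


class TestBandSnp:
    @pytest.mark.parametrize(
        "vaf,band",
        [
            (50.0, ZygosityBand.HET),
            (2.0, ZygosityBand.HOM_REF),
            (30.0, ZygosityBand.DEVIANT),
            (45.0, ZygosityBand.HET),  # boundary inclusive
            (55.0, ZygosityBand.HET),
            (0.0, ZygosityBand.HOM_REF),
            (5.0, ZygosityBand.HOM_REF),
            (95.0, ZygosityBand.HOM_ALT),
            (100.0, ZygosityBand.HOM_ALT),
            (5.001, ZygosityBand.DEVIANT),
            (94.999, ZygosityBand.DEVIANT),
        ],
    )
    def test_examples(self, vaf, band):
        assert band_snp(vaf) is band

    @pytest.mark.parametrize("vaf", [-0.1, 100.1])
    def test_domain_error(self, vaf):
        with pytest.raises(ValueError):
            band_snp(vaf)

    @given(st.floats(0, 100, allow_nan=False))
    def test_total_function(self, vaf):
        assert band_snp(vaf) in set(ZygosityBand)

    def test_bands_must_be_disjoint(self):
        with pytest.raises(ValueError):
            BandConfig(hom_low=(0, 50), het=(45, 55))


class TestCallChromosome:
    def test_balanced_reference_like(self):
        vafs = [50, 49, 51, 2, 98, 50.4, 47, 53, 1, 99]
        call = call_chromosome([obs(v) for v in vafs])
        assert call.status is ImbalanceStatus.BALANCED
        assert call.n_snps == 10
        assert call.n_deviant == 0

    def test_all_homozygous_non_informative(self):
        call = call_chromosome([obs(v) for v in [1, 2, 0, 99, 98, 100, 3, 97, 1, 99]])
        assert call.status is ImbalanceStatus.NON_INFORMATIVE

    def test_monosomy_at_purity_090(self):
        # germline-het loci under monosomy at purity 0.90:
        # retained-ref VAF = (1-p)/(2-p) ~ 9.1%, retained-alt = 1/(2-p) ~ 90.9%
        low, high = 100 * 0.1 / 1.1, 100 * 1 / 1.1
        assert low == pytest.approx(9.0909, abs=1e-3)
        assert high == pytest.approx(90.9091, abs=1e-3)
        vafs = [low, high, low, high, 2, 98]
        call = call_chromosome([obs(v) for v in vafs])
        assert call.status is ImbalanceStatus.IMBALANCED
        assert call.n_deviant == 4

    def test_single_deviant_snp_not_enough(self):
        call = call_chromosome([obs(v) for v in [30, 50, 50, 50, 50]])
        assert call.status is ImbalanceStatus.BALANCED

    def test_minority_deviants_stay_balanced(self):
        call = call_chromosome([obs(v) for v in [30, 35, 50, 50, 50, 50, 50]])
        assert call.status is ImbalanceStatus.BALANCED  # 2/7 informative < 0.5

    def test_empty_input_non_informative(self):
        call = call_chromosome([], patient_id="P1", chrom="3")
        assert call.status is ImbalanceStatus.NON_INFORMATIVE
        assert call.n_snps == 0

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            call_chromosome([obs(50, chrom="1"), obs(50, chrom="3")])

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError, match="patient"):
            call_chromosome([obs(50, patient="A"), obs(50, patient="B")])

    def test_counts_partition(self):
        call = call_chromosome([obs(v) for v in [2, 50, 30, 98, 70]])
        assert call.n_homozygous + call.n_het + call.n_deviant == call.n_snps

    def test_arm_level_subcalls_reported(self):
        snps = [obs(9, arm="p") for _ in range(3)] + [obs(50, arm="q") for _ in range(3)]
        call = call_chromosome(snps)
        assert call.arm_status["p"] is ImbalanceStatus.IMBALANCED
        assert call.arm_status["q"] is ImbalanceStatus.BALANCED


@settings(max_examples=150, deadline=None)
@given(st.lists(st.integers(0, 500), min_size=1, max_size=20))
def test_ref_alt_symmetry(alts):
    """Relabelling ref/alt (vaf -> 100-vaf) never changes the status."""

    def build(alt_counts):
        return [
            SnpObservation("P1", SnpLocus(f"rs{i}", "3", "p", 1000 + i), 500, a)
            for i, a in enumerate(alt_counts)
        ]

    a = call_chromosome(build(alts))
    b = call_chromosome(build([500 - x for x in alts]))
    assert a.status is b.status


class TestSeededAccuracy:
    def test_specificity_pure_disomy(self):
        """>= 99% BALANCED over 1000 disomic chromosomes at depth 500."""
        rng = np.random.default_rng(1234)
        balanced = 0
        for _ in range(1000):
            vafs = 100 * rng.binomial(500, 0.5, size=10) / 500
            call = call_chromosome([obs(v) for v in vafs])
            balanced += call.status is ImbalanceStatus.BALANCED
        assert balanced >= 990

    def test_sensitivity_monosomy(self):
        """>= 99% IMBALANCED for monosomy at the stated purity bound 0.85.

        The imbalance signal weakens as purity falls, so the bound is the
        hardest purity within the attenuation model; near-complete purity
        instead pushes shifted VAFs into the homozygous bands (see ledger).
        """
        rng = np.random.default_rng(5678)
        purity = 0.85
        lo, hi = (1 - purity) / (2 - purity), 1 / (2 - purity)
        detected = 0
        for _ in range(1000):
            n_het = rng.integers(2, 11)
            probs = rng.choice([lo, hi], size=n_het)
            vafs = 100 * rng.binomial(500, probs) / 500
            call = call_chromosome([obs(v) for v in vafs])
            detected += call.status is ImbalanceStatus.IMBALANCED
        assert detected >= 990


class TestPatientCalls:
    def _patient_snps(self, panel, states, purity=0.90, depth=500, seed=0):
        rng = np.random.default_rng(seed)
        snps = []
        for locus in panel.snps:
            state = states[locus.chrom]
            if state == "disomy":
                p = 0.5
            else:
                p = (1 - purity) / (2 - purity) if rng.random() < 0.5 else 1 / (2 - purity)
            snps.append(
                SnpObservation("P1", locus, depth, int(rng.binomial(depth, p)))
            )
        return snps

    def test_all_balanced(self, panel):
        snps = self._patient_snps(panel, {"1": "disomy", "3": "disomy", "8": "disomy"})
        calls = call_patient_imbalances(snps, panel)
        assert {c: calls[c].status for c in "138"} == {
            c: ImbalanceStatus.BALANCED for c in "138"
        }

    def test_monosomy_3_only(self, panel):
        snps = self._patient_snps(panel, {"1": "disomy", "3": "monosomy", "8": "disomy"})
        calls = call_patient_imbalances(snps, panel)
        assert calls["3"].status is ImbalanceStatus.IMBALANCED
        assert calls["1"].status is ImbalanceStatus.BALANCED
        assert calls["8"].status is ImbalanceStatus.BALANCED

    def test_missing_chromosome_non_informative(self, panel):
        snps = [
            s for s in self._patient_snps(panel, {"1": "disomy", "3": "disomy", "8": "disomy"})
            if s.locus.chrom != "8"
        ]
        calls = call_patient_imbalances(snps, panel)
        assert calls["8"].status is ImbalanceStatus.NON_INFORMATIVE

    def test_unknown_locus_ignored_with_warning(self, panel, caplog):
        snps = self._patient_snps(panel, {"1": "disomy", "3": "disomy", "8": "disomy"})
        rogue = SnpObservation("P1", SnpLocus("rs9999999", "3", "p", 123), 500, 250)
        with caplog.at_level("WARNING"):
            calls = call_patient_imbalances(snps + [rogue], panel)
        assert "rs9999999" in caplog.text
        assert calls["3"].n_snps == sum(1 for s in panel.snps if s.chrom == "3")
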