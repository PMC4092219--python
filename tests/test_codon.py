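"""Codon-usage indices: counts, GC3, Wright's Nc, RSCU, CAI."""

import math
import random

import numpy as np
import pytest

from singlecopy.codon import (
    FAMILIES,
    SENSE_CODONS,
    CodonCounts,
    ReferenceWeights,
    cai,
    count_codons,
    gc3,
    gene_metrics,
    nc,
    reference_weights,
    rscu,
)

EXTREME_BIAS_CDS = "".join(sorted(fam)[0] * 2 for fam in FAMILIES.values())
UNIFORM_CDS = "".join(c * 2 for c in SENSE_CODONS)


class TestCounts:
    def test_terminal_stop_trimmed(self):
        cc = count_codons("ATGTAA")
        assert cc.counts == {"ATG": 1}
        assert not cc.has_internal_stop

    def test_ambiguous_codons_skipped(self):
        cc = count_codons("ATGNNNAAA")
        assert cc.counts == {"ATG": 1, "AAA": 1}
        assert cc.n_ambiguous == 1

    def test_internal_stop_flagged(self):
        cc = count_codons("ATGTAAAAA")
        assert cc.has_internal_stop

    @pytest.mark.parametrize("bad", ["", "ATGA"])
    def test_invalid_cds_raises(self, bad):
        with pytest.raises(ValueError):
            count_codons(bad)


class TestGc3:
    @pytest.mark.parametrize(
        "cds,expected", [("GGGCCC", 1.0), ("AAATTT", 0.0), ("AAAGGG", 0.5)]
    )
    def test_closed_form(self, cds, expected):
        assert gc3(count_codons(cds)) == expected

    def test_no_sense_codons_missing(self):
        assert gc3(CodonCounts()) is None


def _oracle_nc(counts: dict[str, int]) -> float | None:
    """Independent homozygosity-by-family transcription of Wright's estimator."""
    from singlecopy.io_formats import CODON_TABLE

    fam_of: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE.items():
        if aa != "*":
            fam_of.setdefault(aa, []).append(codon)
    by_size: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in fam_of.items():
        size = len(codons)
        if size == 1:
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            by_size[size].append(f)
    total = 2.0
    for size, weight in ((2, 9), (3, 1), (4, 5), (6, 3)):
        if not by_size[size]:
            return None
        total += weight / (sum(by_size[size]) / len(by_size[size]))
    return min(max(total, 20.0), 61.0)


class TestNc:
    def test_one_codon_per_amino_acid_gives_twenty(self):
        assert nc(count_codons(EXTREME_BIAS_CDS)) == 20.0

    def test_uniform_synonymous_usage_gives_sixty_one(self):
        assert nc(count_codons(UNIFORM_CDS)) == 61.0

    def test_matches_homozygosity_oracle_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            counts = {
                c: int(rng.integers(0, 12)) for c in SENSE_CODONS
            }
            cc = CodonCounts(counts={k: v for k, v in counts.items() if v})
            ours = nc(cc)
            oracle = _oracle_nc(counts)
            if oracle is None:
                assert ours is None
            else:
                assert ours == pytest.approx(oracle, abs=1e-9)

    def test_missing_redundancy_class_gives_none(self):
        # only Phe codons observed: 3-, 4- and 6-fold classes empty
        assert nc(CodonCounts(counts={"TTT": 5, "TTC": 5})) is None

    def test_invariant_under_codon_permutation(self):
        rng = random.Random(13)
        codons = [rng.choice(SENSE_CODONS) for _ in range(150)]
        a = nc(count_codons("".join(codons)))
        rng.shuffle(codons)
        b = nc(count_codons("".join(codons)))
        assert a == b

    def test_bounds_hold_on_random_sequences(self):
        rng = random.Random(17)
        for _ in range(20):
            cds = "".join(rng.choice(SENSE_CODONS) for _ in range(100))
            val = nc(count_codons(cds))
            if val is not None:
                assert 20.0 <= val <= 61.0


class TestRscu:
    def test_equal_usage_gives_ones(self):
        cc = count_codons("GGTGGCGGAGGG")  # Gly family, once each
        vals = rscu(cc)
        assert all(vals[c] == 1.0 for c in FAMILIES["G"])

    def test_single_codon_of_twofold_family(self):
        cc = count_codons("TTTTTT")  # Phe: TTT twice, TTC zero
        vals = rscu(cc)
        assert vals["TTT"] == 2.0 and vals["TTC"] == 0.0

    def test_sums_to_family_size(self):
        rng = random.Random(23)
        cds = "".join(rng.choice(SENSE_CODONS) for _ in range(200))
        vals = rscu(count_codons(cds))
        for aa, fam in FAMILIES.items():
            present = [vals[c] for c in fam if c in vals]
            if present:
                assert sum(present) == pytest.approx(len(fam))

    def test_absent_family_missing(self):
        vals = rscu(count_codons("TTTTTC"))
        assert "GGT" not in vals


class TestReferenceWeights:
    def test_preferred_codon_gets_weight_one(self):
        w = reference_weights(["TTTTTTTTC"])  # TTT 2x, TTC 1x
        assert w.w["TTT"] == 1.0
        assert w.w["TTC"] == pytest.approx(0.5)

    def test_unobserved_codon_smoothed(self):
        w = reference_weights(["TTTTTT"])  # TTC unobserved
        assert w.w["TTC"] == pytest.approx(0.5 / 2)

    def test_pooling_scale_invariance(self):
        one = reference_weights(["TTTTTCGGAGGG"])
        two = reference_weights(["TTTTTCGGAGGG"] * 2)
        assert one.w == two.w

    def test_recovers_simulated_preferred_codons(self):
        from singlecopy.simulate import ClassModel, _codon_weights, _sample_cds

        rng = np.random.default_rng(3)
        model = ClassModel(omega=0.1, target_gc3=0.3, codon_bias=10.0, dup_rate=0, loss_rate=0)
        weights = _codon_weights(model)
        refs = [_sample_cds(300, weights, rng) for _ in range(30)]
        w = reference_weights(refs)
        for aa, fam in FAMILIES.items():
            if len(fam) == 1:
                continue
            planted = fam[int(np.argmax(weights[aa]))]
            top = max((c for c in fam if c in w.w), key=lambda c: w.w[c])
            assert top == planted, f"{aa}: {top} != {planted}"

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            reference_weights([])


class TestCai:
    def test_all_maximal_weights_give_one(self):
        w = ReferenceWeights(w={"TTT": 1.0, "TTC": 0.5})
        assert cai(count_codons("TTTTTT"), w) == pytest.approx(1.0)

    def test_geometric_mean_closed_form(self):
        w = ReferenceWeights(w={"TTT": 1.0, "TTC": 0.25})
        assert cai(count_codons("TTTTTC"), w) == pytest.approx(0.5)

    def test_met_trp_excluded(self):
        w = ReferenceWeights(w={"TTT": 1.0, "TTC": 0.25})
        # adding ATG/TGG does not change the index
        assert cai(count_codons("TTTTTCATGTGG"), w) == pytest.approx(0.5)

    def test_matches_log_domain_oracle(self):
        rng = random.Random(29)
        pool = [c for c in SENSE_CODONS]
        wmap = {}
        for fam in FAMILIES.values():
            mx = rng.choice(fam)
            for c in fam:
                wmap[c] = 1.0 if c == mx else rng.uniform(0.05, 0.9)
        weights = ReferenceWeights(w=wmap)
        from singlecopy.codon import SINGLE_CODON_AAS
        from singlecopy.io_formats import CODON_TABLE

        for _ in range(10):
            cds = "".join(rng.choice(pool) for _ in range(120))
            cc = count_codons(cds)
            logs = [
                math.log(wmap[c]) * n
                for c, n in cc.counts.items()
                if CODON_TABLE[c] not in SINGLE_CODON_AAS
            ]
            ns = sum(
                n for c, n in cc.counts.items()
                if CODON_TABLE[c] not in SINGLE_CODON_AAS
            )
            oracle = math.exp(sum(logs) / ns)
            assert cai(cc, weights) == pytest.approx(oracle, abs=1e-12)

    def test_no_eligible_codons_missing(self):
        w = ReferenceWeights(w={"TTT": 1.0})
        assert cai(count_codons("ATGTGG"), w) is None


class TestGeneMetrics:
    def test_bundles_all_indices(self):
        w = reference_weights([UNIFORM_CDS])
        m = gene_metrics("g1", EXTREME_BIAS_CDS, w)
        assert m.nc == 20.0
        assert m.gc3 is not None and 0 <= m.gc3 <= 1
        assert m.cai is not None and 0 < m.cai <= 1


class TestClassComparison:
    def test_mann_whitney_detects_planted_class_contrast(self):
        """With 200+ genes per class, Nc and GC3 differences between the
        biased (single-copy-like) and unbiased (family-like) codon models
        are detected in the planted direction at alpha = 0.05."""
        from singlecopy.simulate import ClassModel, _codon_weights, _sample_cds
        from singlecopy.stats import mann_whitney

        rng = np.random.default_rng(55)
        biased = _codon_weights(
            ClassModel(omega=0.1, target_gc3=0.3, codon_bias=8.0, dup_rate=0, loss_rate=0)
        )
        unbiased = _codon_weights(
            ClassModel(omega=0.5, target_gc3=0.6, codon_bias=1.0, dup_rate=0, loss_rate=0)
        )
        metrics = {"biased": {"nc": [], "gc3": []}, "unbiased": {"nc": [], "gc3": []}}
        for label, w in (("biased", biased), ("unbiased", unbiased)):
            for _ in range(200):
                cc = count_codons(_sample_cds(120, w, rng))
                val = nc(cc)
                if val is not None:
                    metrics[label]["nc"].append(val)
                metrics[label]["gc3"].append(gc3(cc))
        for index in ("nc", "gc3"):
            x = metrics["biased"][index]
            y = metrics["unbiased"][index]
            _, p = mann_whitney(x, y)
            assert p < 0.05
            assert np.median(x) < np.median(y)
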