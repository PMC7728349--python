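"""Target-decoy q-values, confidence classes, aggregation and filtering."""

import numpy as np
import pandas as pd
import pytest

from cobindkit.psm import (
    FilterConfig,
    aggregate_proteins,
    apply_delta_cn_filter,
    classify_confidence,
    compute_psm_qvalues,
    filter_interactors,
)
from cobindkit.simulate import PsmSimConfig, simulate_psms
from cobindkit.swisnf import SWISNF_SUBUNITS, annotate_swisnf


def make_psms(scores, decoys, **extra):
    n = len(scores)
    frame = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "peptide": [f"PEP{i}" for i in range(n)],
            "accession": ["P00001"] * n,
            "score": scores,
            "delta_cn": 0.0,
            "is_decoy": decoys,
            "sample": "benzonase",
            "replicate": 1,
        }
    )
    for key, val in extra.items():
        frame[key] = val
    return frame


def brute_force_qvalues(t_scores, d_scores):
    """Exhaustive threshold enumeration: q(s) = min over thresholds s' <= s
    of #decoys>=s' / max(1, #targets>=s')."""
    out = []
    for s in t_scores:
        fdrs = [
            sum(1 for d in d_scores if d >= s2) / max(1, sum(1 for t in t_scores if t >= s2))
            for s2 in t_scores
            if s2 <= s
        ]
        out.append(min(min(fdrs), 1.0))
    return out


class TestQvalues:
    def test_worked_example_matches_enumeration_oracle(self):
        frame = make_psms([10, 9, 8, 7, 8.5, 6], [False] * 4 + [True] * 2)
        got = compute_psm_qvalues(frame)
        target_q = got.loc[~got.is_decoy, "q_value"].tolist()
        assert target_q == [0.0, 0.0, 0.25, 0.25]
        assert target_q == brute_force_qvalues([10, 9, 8, 7], [8.5, 6])

    def test_targets_only_all_zero(self):
        frame = make_psms([5.0, 1.0, 3.0], [False] * 3)
        got = compute_psm_qvalues(frame)
        assert (got["q_value"] == 0.0).all()

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            n_t, n_d = int(rng.integers(1, 25)), int(rng.integers(1, 25))
            t = np.round(rng.normal(1, 2, n_t), 2)
            d = np.round(rng.normal(0, 2, n_d), 2)
            frame = make_psms(
                np.concatenate([t, d]), [False] * n_t + [True] * n_d
            )
            got = compute_psm_qvalues(frame)
            expect = brute_force_qvalues(list(t), list(d))
            assert got.loc[~got.is_decoy, "q_value"].tolist() == pytest.approx(expect)

    def test_q_monotone_in_score(self):
        cfg = PsmSimConfig(n_targets=500, n_decoys=500, seed=5)
        got = compute_psm_qvalues(simulate_psms(cfg))
        targets = got.loc[~got.is_decoy].sort_values("score", ascending=False)
        q = targets["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()


class TestConfidenceClasses:
    @pytest.mark.parametrize(
        "q,expected",
        [
            (0.005, "high"),
            (0.0, "high"),
            (0.01, "medium"),  # strict boundary is exclusive for high
            (0.03, "medium"),
            (0.05, "rejected"),  # relaxed boundary is exclusive for medium
            (0.5, "rejected"),
            (1.0, "rejected"),
        ],
    )
    def test_class_boundaries(self, q, expected):
        assert classify_confidence(q) == expected

    def test_q_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_confidence(1.5)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            FilterConfig(strict_fdr=0.05, relaxed_fdr=0.01)


class TestDeltaCnFilter:
    def test_drops_only_above_cap(self):
        frame = make_psms([1, 2, 3], [False] * 3)
        frame["delta_cn"] = [0.0, 0.05, 0.06]
        kept = apply_delta_cn_filter(frame, 0.05)
        assert len(kept) == 2


class TestAggregateProteins:
    def test_peptide_and_psm_counting(self):
        frame = make_psms([10, 11, 12], [False] * 3)
        frame["peptide"] = ["A", "A", "B"]
        got = aggregate_proteins(compute_psm_qvalues(frame))
        assert got.loc[0, "mean_peptides_benzonase"] == 2.0
        assert got.loc[0, "mean_psms_benzonase"] == 3.0

    def test_mean_over_replicate_injections(self):
        # injection 1: 3 peptides / 5 PSMs; injection 2: 5 peptides / 7 PSMs
        peptides = ["A", "B", "C", "A", "B"] + ["A", "B", "C", "D", "E", "A", "B"]
        replicate = [1] * 5 + [2] * 7
        frame = make_psms([10.0] * 12, [False] * 12)
        frame["peptide"] = peptides
        frame["replicate"] = replicate
        got = aggregate_proteins(compute_psm_qvalues(frame))
        assert got.loc[0, "mean_peptides_benzonase"] == 4.0
        assert got.loc[0, "mean_psms_benzonase"] == 6.0

    def test_single_peptide_flag(self):
        frame = make_psms([10, 10], [False, False])
        frame["peptide"] = ["A", "A"]
        frame["sample"] = ["benzonase", "untreated"]
        got = aggregate_proteins(compute_psm_qvalues(frame))
        assert bool(got.loc[0, "single_peptide_flag"])

    def test_psm_count_conserved(self):
        cfg = PsmSimConfig(n_targets=300, n_decoys=300, seed=9)
        psms = compute_psm_qvalues(simulate_psms(cfg))
        got = aggregate_proteins(psms)
        total = got[[c for c in got.columns if c.startswith("mean_psms_")]].sum().sum()
        assert total == pytest.approx((~psms.is_decoy).sum())

    def test_requires_qvalues(self):
        with pytest.raises(ValueError):
            aggregate_proteins(make_psms([1.0], [False]))


class TestFilterInteractors:
    def _protein_table(self, rows):
        return pd.DataFrame(
            rows, columns=["accession", "protein_q", "confidence", "single_peptide_flag"]
        )

    def test_control_presence_excludes(self):
        ip = self._protein_table([("P1", 0.0, "high", False), ("P2", 0.0, "high", False)])
        control = self._protein_table([("P2", 0.2, "rejected", True)])
        got = filter_interactors(ip, control)
        assert got["accession"].tolist() == ["P1"]

    def test_contaminant_excluded(self):
        ip = self._protein_table([("P1", 0.0, "high", False), ("KRT1", 0.0, "high", False)])
        cfg = FilterConfig(contaminants=frozenset({"KRT1"}))
        got = filter_interactors(ip, None, cfg)
        assert got["accession"].tolist() == ["P1"]

    def test_only_high_confidence_retained(self):
        ip = self._protein_table(
            [("P1", 0.005, "high", False), ("P2", 0.03, "medium", False)]
        )
        got = filter_interactors(ip, None)
        assert got["accession"].tolist() == ["P1"]

    def test_idempotent_and_subset(self):
        ip = self._protein_table(
            [("P1", 0.0, "high", False), ("P2", 0.03, "medium", False), ("P3", 0.0, "high", False)]
        )
        control = self._protein_table([("P3", 0.5, "rejected", False)])
        once = filter_interactors(ip, control)
        twice = filter_interactors(once, control)
        assert once.equals(twice)
        assert set(once["accession"]) <= set(ip["accession"])

    def test_empty_ip_passes_through(self):
        empty = self._protein_table([])
        assert filter_interactors(empty, None).empty


class TestSwisnfAnnotation:
    def test_known_signature_subunits(self):
        brd9 = annotate_swisnf("Q9H8M2")
        assert brd9.role == "signature" and brd9.complexes == ("ncBAF",)
        arid1a = annotate_swisnf("O14497")
        assert arid1a.role == "signature" and arid1a.complexes == ("BAF",)

    def test_core_subunit_absent_from_ncbaf(self):
        baf57 = annotate_swisnf("Q969G3")
        assert baf57.role == "core"
        assert baf57.in_baf and baf57.in_pbaf and not baf57.in_ncbaf

    def test_unknown_accession_unannotated(self):
        assert annotate_swisnf("NOPE123") is None

    def test_table_covers_29_subunits(self):
        assert len(SWISNF_SUBUNITS) == 29
        roles = {a.role for a in SWISNF_SUBUNITS.values()}
        assert roles == {"core", "signature", "accessory"}
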