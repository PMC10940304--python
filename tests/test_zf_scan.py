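"""Domain detection, QALGGH typing, and architecture classification."""

import pytest

from zfscan import synthetic_data, zf_scan
from zfscan.io_formats import SequenceRecord
from zfscan.zf_scan import (
    TANDEM_MAX_LINKER,
    ZFDomain,
    assign_names,
    build_architecture,
    classify_architecture,
    degradation_count,
    scan_domains,
    summarize_family,
)


def make_domain(start, type_label, deg=None):
    """A synthetic ZFDomain at a given start with realistic geometry."""
    if deg is None:
        deg = 0 if type_label == "Q" else (int(type_label[1]) if type_label.startswith("M") else 0)
    his2 = None if type_label == "D" else start + 21
    last = start + 16 if his2 is None else his2
    return ZFDomain(
        start=start, end=last + 1, cys1=start, cys2=start + 3,
        his1=start + 16, his2=his2, qalggh_window="QALGGH",
        degradation=deg, type_label=type_label,
    )


def chain(types, linkers):
    """Domains laid out with the requested linker lengths."""
    domains = []
    pos = 0
    for i, t in enumerate(types):
        d = make_domain(pos, t)
        domains.append(d)
        pos = d.last_coordinating + 1 + (linkers[i] if i < len(linkers) else 0)
    return domains


class TestScan:
    @pytest.mark.parametrize(
        "seq,n,type_label,deg",
        [
            ("AACAACAAAAAAAQALGGHAAAH", 1, "Q", 0),
            ("AACAACAAAAAAAAALGGHAAAH", 1, "M1", 1),
            ("AACAACAAAAAAAQALGGHAAAG", 1, "D", 0),
        ],
    )
    def test_canonical_patterns(self, seq, n, type_label, deg):
        domains = scan_domains(seq)
        assert len(domains) == n
        assert domains[0].type_label == type_label
        assert domains[0].degradation == deg

    def test_no_cys_his_means_no_domain(self):
        assert scan_domains("A" * 80) == []

    def test_coordinating_geometry(self):
        (d,) = scan_domains("AACAACAAAAAAAQALGGHAAAH")
        assert d.cys1 < d.cys2 < d.his1 < d.his2
        assert 3 <= d.cys2 - d.cys1 <= 5
        assert d.his1 - d.cys2 == 13
        assert 4 <= d.his2 - d.his1 <= 6

    def test_x_in_coordinating_position_never_matches(self):
        (d,) = scan_domains("AACAACAAAAAAAQALGGHAAAH")
        broken = "AAXAACAAAAAAAQALGGHAAAH"  # first Cys replaced by X
        assert scan_domains(broken) == []

    def test_determinism(self, proteome):
        records, _ = proteome
        for rec in records[:5]:
            assert scan_domains(rec) == scan_domains(rec)


class TestDegradation:
    @pytest.mark.parametrize(
        "window,expected",
        [("QALGGH", 0), ("AALGGH", 1), ("AAAGGA", 3), ("VVVVVV", 6)],
    )
    def test_hamming(self, window, expected):
        assert degradation_count(window) == expected

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            degradation_count("QALGG")


class TestClassification:
    @pytest.mark.parametrize(
        "types,linkers,expected",
        [
            (["Q"], [], "1i-Q"),
            (["Q", "Q"], [30], "2i-Q"),
            (["M1", "M2", "Q"], [5, 40], "t1-Mx"),
            (["Q", "M1", "M3", "Q"], [8, 30, 30], "t2-Mx"),
            (["M2", "M2", "M2"], [20, 25], "3i-M"),
            (["D", "D"], [15], "2i-D"),
            (["Q", "M1"], [12], "2i-Mx"),
        ],
    )
    def test_subgroups(self, types, linkers, expected):
        assert classify_architecture(chain(types, linkers)) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_architecture([])

    def test_tandem_boundary_flip(self):
        """Shrinking one linker from 12 to 11 flips 3i-* to t1-* and back."""
        assert classify_architecture(chain(["Q", "Q", "Q"], [12, 20])) == "3i-Q"
        assert classify_architecture(chain(["Q", "Q", "Q"], [11, 20])) == "t1-Q"
        assert classify_architecture(chain(["Q", "Q", "Q"], [12, 20])) == "3i-Q"

    def test_two_tandem_domains_stay_2i(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="zfscan.zf_scan"):
            label = classify_architecture(chain(["Q", "Q"], [5]))
        assert label == "2i-Q"
        assert any("tandem spacing" in r.message for r in caplog.records)


class TestNaming:
    def _arches(self):
        recs = [
            SequenceRecord("gx", "AAA" + "CAACAAAAAAAQALGGHAAAH" + "A" * 30
                           + "CAACAAAAAAAQALGGHAAAH" + "AAA"),
            SequenceRecord("gy", "AAA" + "CAACAAAAAAAQALGGHAAAH" + "A" * 30
                           + "CAACAAAAAAAQALGGHAAAH" + "AAA"),
            SequenceRecord("gz", "AAACAACAAAAAAAQALGGHAAAHAAA"),
        ]
        return [build_architecture(r) for r in recs]

    def test_genomic_order_within_subgroup(self):
        arches = self._arches()
        names = assign_names(
            arches, {"gx": ("chr3", 10), "gy": ("chr1", 99), "gz": ("chr1", 5)}
        )
        assert names["gy"] == "C2H2.2i-Q.01"  # chr1 before chr3
        assert names["gx"] == "C2H2.2i-Q.02"
        assert names["gz"] == "C2H2.1i-Q.01"
        assert len(set(names.values())) == len(names)

    def test_duplicate_gene_id_raises(self):
        arches = self._arches()
        arches[1].protein_id = "gx"
        with pytest.raises(ValueError, match="duplicate"):
            assign_names(arches, {"gx": ("chr1", 1), "gz": ("chr1", 2)})


class TestSummary:
    def test_counts_partition_input(self):
        arches = [
            zf_scan.ProteinArchitecture("a", [make_domain(0, "Q")], subgroup="1i-Q"),
            zf_scan.ProteinArchitecture("b", [make_domain(0, "Q")], subgroup="1i-Q"),
            zf_scan.ProteinArchitecture("c", [make_domain(0, "M1")], subgroup="2i-M"),
        ]
        table = summarize_family(arches)
        by = dict(zip(table["subgroup"], table["n_proteins"]))
        assert by == {"1i-Q": 2, "2i-M": 1, "total": 3}

    def test_empty(self):
        table = summarize_family([])
        assert list(table["n_proteins"]) == [0]

    def test_synthetic_family_matches_generator_plan(self, proteome, default_spec):
        records, _ = proteome
        arches = [build_architecture(r) for r in records]
        table = summarize_family(arches)
        by = dict(zip(table["subgroup"], table["n_proteins"]))
        total = by.pop("total")
        assert total == default_spec.n_genes
        assert by == default_spec.architecture_mix


class TestRecovery:
    def test_full_planted_recovery(self, proteome):
        """Type, coordinates, and subgroup recovered for every planted gene."""
        records, truth = proteome
        for rec in records:
            arch = build_architecture(rec)
            want = truth[rec.id]
            assert arch.subgroup == want["subgroup"]
            got = [(d.start, d.end, d.type_label) for d in arch.domains]
            assert got == [(d["start"], d["end"], d["type"]) for d in want["domains"]]
            assert arch.linker_lengths == want["linkers"]

    def test_tandem_flags_match_linkers(self, proteome):
        records, _ = proteome
        for rec in records:
            arch = build_architecture(rec)
            assert arch.tandem_flags == [
                l <= TANDEM_MAX_LINKER for l in arch.linker_lengths
            ]

    def test_degradation_bounds_and_q_iff_zero(self, proteome):
        records, _ = proteome
        for rec in records:
            for d in scan_domains(rec):
                assert 0 <= d.degradation <= 6
                if d.his2 is not None:
                    assert (d.type_label == "Q") == (d.degradation == 0)
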