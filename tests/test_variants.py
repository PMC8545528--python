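"""Variant overlay: LD filter, region classes, site calls, ceRNA effects."""

import numpy as np
import pandas as pd
import pytest

from netdissect import synth, variants
from netdissect.errors import ValidationError
from netdissect.graph import TypedGraph
from netdissect.variants import SiteEvent, revcomp, seed_site


def snp_frame(rows):
    return pd.DataFrame(rows, columns=variants.SNP_COLUMNS)


def test_ld_filter_strict_threshold():
    snps = snp_frame([
        ("rs1", "L1", 10, "A", "C", "lncRNA", 0.85),
        ("rs2", "L1", 50, "A", "C", "TFBS", 0.80),
        ("rs3", "L1", 90, "A", "C", "DHS", 0.79),
        ("rs4", "L1", 130, "A", "C", "enhancer", np.nan),  # lead SNP
    ])
    kept = variants.ld_filter(snps)
    assert sorted(kept["snp_id"]) == ["rs1", "rs4"]
    # inclusive mode keeps the boundary value
    inc = variants.ld_filter(snps, inclusive=True)
    assert sorted(inc["snp_id"]) == ["rs1", "rs2", "rs4"]
    assert len(variants.ld_filter(snps, r2_threshold=0.0)) == 4
    assert variants.ld_filter(snps.iloc[:0]).empty


def test_ld_filter_monotone_and_lead_safe():
    rng = np.random.default_rng(8)
    snps = snp_frame([
        (f"rs{i}", "L1", i * 50 % 400, "A", "G", "TAD",
         np.nan if i % 5 == 0 else float(rng.uniform()))
        for i in range(40)
    ])
    leads = set(snps[snps["ld_r2"].isna()]["snp_id"])
    prev = len(snps) + 1
    for thr in (0.0, 0.3, 0.6, 0.9, 1.0):
        kept = variants.ld_filter(snps, thr)
        assert leads <= set(kept["snp_id"])
        assert len(kept) <= prev
        prev = len(kept)


def test_classify_regions_half_open_multilabel():
    intervals = pd.DataFrame(
        [("L1", 100, 200, "TFBS"), ("L1", 150, 260, "DHS"),
         ("L1", 300, 320, "enhancer")],
        columns=["lncrna_id", "start", "end", "region_class"],
    )
    snps = snp_frame([
        ("rs1", "L1", 150, "A", "C", "lncRNA", np.nan),  # TFBS + DHS
        ("rs2", "L1", 200, "A", "C", "lncRNA", np.nan),  # half-open: DHS only
        ("rs3", "L1", 10, "A", "C", "lncRNA", np.nan),   # nothing
    ])
    out, summary = variants.classify_regions(snps, intervals)
    assert out.loc[0, "region_classes"] == ("DHS", "TFBS")
    assert out.loc[1, "region_classes"] == ("DHS",)
    assert out.loc[2, "region_classes"] == ()
    assert summary["class_counts"] == {"DHS": 2, "TFBS": 1}
    assert sum(summary["class_proportions"].values()) == pytest.approx(1.0)

    bad = intervals.copy()
    bad.loc[0, "end"] = 100
    with pytest.raises(ValidationError):
        variants.classify_regions(snps, bad)


def test_classify_regions_matches_bruteforce():
    rng = np.random.default_rng(4)
    intervals = pd.DataFrame(
        [(f"L{i % 3}", int(s), int(s + rng.integers(5, 80)),
          cls)
         for i, (s, cls) in enumerate(zip(
             rng.integers(0, 350, 30),
             rng.choice(variants.REGION_CLASSES, 30)))],
        columns=["lncrna_id", "start", "end", "region_class"],
    )
    snps = snp_frame([
        (f"rs{i}", f"L{int(rng.integers(3))}", int(rng.integers(0, 400)),
         "A", "C", "lncRNA", np.nan)
        for i in range(50)
    ])
    out, _ = variants.classify_regions(snps, intervals)
    for _, row in out.iterrows():
        expected = sorted({
            iv.region_class for iv in intervals.itertuples()
            if iv.lncrna_id == row["lncrna_id"]
            and iv.start <= row["pos"] < iv.end
        })
        assert list(row["region_classes"]) == expected


MIRNA_SEED = "TAGCTTAT"  # positions 1-8; site = revcomp(seed[1:8])


def gain_fixture():
    site = seed_site(MIRNA_SEED)  # 7-mer target site
    pos, offset = 50, 3
    seq = list("ACGT" * 30)
    start = pos - offset
    seq[start:start + 7] = site
    alt = site[offset]
    ref = "G" if alt != "G" else "C"
    seq[pos] = ref
    snp = {"snp_id": "rs_g", "lncrna_id": "L1", "pos": pos,
           "ref": ref, "alt": alt, "region_class": "lncRNA"}
    return "".join(seq), snp, start


def test_mirna_site_gain_called():
    seq, snp, start = gain_fixture()
    events = variants.mirna_site_call(seq, snp, {"miR-X": MIRNA_SEED})
    assert events == [SiteEvent("rs_g", "L1", "miR-X", "mirna_site",
                                "gain", snp["alt"], start)]
    # under a seed dictionary with no matching site: silence
    assert variants.mirna_site_call(seq, snp, {"miR-Y": "GGGGGGGG"}) == []


def test_mirna_site_loss_called():
    site = seed_site(MIRNA_SEED)
    pos, offset = 21, 6
    seq = list("TTTTAAAACCCCGGGG" * 8)
    start = pos - offset
    seq[start:start + 7] = site
    seq[pos] = site[offset]  # reference carries the intact site
    alt = "A" if site[offset] != "A" else "T"
    snp = {"snp_id": "rs_l", "lncrna_id": "L1", "pos": pos,
           "ref": site[offset], "alt": alt, "region_class": "lncRNA"}
    events = variants.mirna_site_call("".join(seq), snp,
                                      {"miR-X": MIRNA_SEED})
    assert [(e.effect, e.allele, e.start) for e in events] == \
        [("loss", site[offset], start)]


def test_mirna_site_position_validation():
    seq, snp, _ = gain_fixture()
    snp_bad = dict(snp, pos=len(seq) + 5)
    with pytest.raises(ValidationError):
        variants.mirna_site_call(seq, snp_bad, {"miR-X": MIRNA_SEED})
    with pytest.raises(ValidationError):
        variants.mirna_site_call(seq, dict(snp, alt=snp["ref"]),
                                 {"miR-X": MIRNA_SEED})


def test_tfbs_iupac_gain_and_neutral():
    # motif GGAW: ref window GGAC does not match, alt GGAA does
    seq = "T" * 30 + "GGAC" + "T" * 30
    snp = {"snp_id": "rs_t", "lncrna_id": "L1", "pos": 33,
           "ref": "C", "alt": "A", "region_class": "TFBS"}
    events = variants.tfbs_call(seq, snp, {"ERG-like": "GGAW"})
    assert [(e.element_id, e.effect, e.start) for e in events] == \
        [("ERG-like", "gain", 30)]
    # motif matching under both alleles: no event
    assert variants.tfbs_call(seq, snp, {"any": "GGAN"}) == []
    with pytest.raises(ValidationError):
        variants.tfbs_call(seq, snp, {"bad": "GGAX"})


def test_tfbs_loss_recovered():
    seq = "C" * 20 + "TGACGTCA" + "C" * 20
    snp = {"snp_id": "rs_t2", "lncrna_id": "L1", "pos": 24,
           "ref": "G", "alt": "T", "region_class": "TFBS"}
    events = variants.tfbs_call(seq, snp, {"CREB-like": "TGACGTCA"})
    assert [(e.effect, e.allele) for e in events] == [("loss", "G")]


def disruption_graph() -> TypedGraph:
    g = TypedGraph()
    g.add_node("L1", "lncRNA")
    g.add_node("L2", "lncRNA")
    for gene, t in [("G1", "common"), ("G2", "DR"), ("G3", "diabetes")]:
        g.add_node(gene, t)
    g.add_edge("L1", "G1", "cerna", ["miR-X"])
    g.add_edge("L1", "G2", "cerna", ["miR-X", "miR-Y"])
    g.add_edge("L2", "G3", "cerna", ["miR-Z"])
    return g


def ev(snp, lnc, mir, effect):
    return SiteEvent(snp, lnc, mir, "mirna_site", effect, "A", 0)


def test_cerna_disruption_loss_semantics():
    g = disruption_graph()
    table = variants.cerna_disruption([ev("rs1", "L1", "miR-X", "loss")], g)
    by_pair = {(r.lncrna, r.gene): r.status for r in table.itertuples()}
    # sole shared miRNA lost -> disrupted; one of two lost -> unchanged
    assert by_pair[("L1", "G1")] == "disrupted"
    assert by_pair[("L1", "G2")] == "unchanged"
    row = table[table["status"] == "disrupted"].iloc[0]
    assert row["causal_snps"] == ["rs1"]

    with pytest.raises(ValidationError):
        variants.cerna_disruption([ev("rs9", "L9", "miR-X", "loss")], g)


def test_cerna_disruption_gain_creates_relation():
    g = disruption_graph()
    # L2 gains a site for miR-Y, which annotates G2 (via L1) but L2-G2
    # has no existing edge -> created
    table = variants.cerna_disruption([ev("rs2", "L2", "miR-Y", "gain")], g)
    created = table[table["status"] == "created"]
    assert [(r.lncrna, r.gene) for r in created.itertuples()] == [("L2", "G2")]
    assert created.iloc[0]["shared_mirnas"] == ["miR-Y"]


def test_two_mirna_gain_scenario():
    """One risk allele completes seed sites for two miRNAs at once, creating
    a lncRNA-gene ceRNA relation shared through both (the rs12108041-style
    double-gain situation)."""
    seed_a = "A" + revcomp("GATCGAT")  # site GATCGAT, SNP at its first base
    seed_b = "A" + revcomp("CCTTAGG")  # site CCTTAGG, SNP at its last base
    site_a, site_b = "GATCGAT", "CCTTAGG"
    assert site_a[0] == site_b[6] == "G"
    pos = 30
    seq = list("T" * 24 + site_b[:6] + "G" + site_a[1:] + "T" * 24)
    seq[pos] = "C"  # reference allele breaks both sites
    snp = {"snp_id": "rs_double", "lncrna_id": "L1", "pos": pos,
           "ref": "C", "alt": "G", "region_class": "lncRNA"}
    events = variants.mirna_site_call(
        "".join(seq), snp, {"miR-A": seed_a, "miR-B": seed_b}
    )
    assert sorted((e.element_id, e.effect) for e in events) == \
        [("miR-A", "gain"), ("miR-B", "gain")]

    g = TypedGraph()
    g.add_node("L1", "lncRNA")
    g.add_node("G_target", "DR")
    table = variants.cerna_disruption(
        events, g, gene_mirnas={"G_target": frozenset({"miR-A", "miR-B"})}
    )
    assert list(table["status"]) == ["created"]
    assert table.iloc[0]["shared_mirnas"] == ["miR-A", "miR-B"]
    assert table.iloc[0]["causal_snps"] == ["rs_double"]
    # strict all-shared mode also satisfied (both sites gained)
    strict = variants.cerna_disruption(
        events, g, gene_mirnas={"G_target": frozenset({"miR-A", "miR-B"})},
        require_all_shared=True,
    )
    assert list(strict["status"]) == ["created"]
    # but a single gain does not create under the strict rule
    strict_one = variants.cerna_disruption(
        events[:1], g, gene_mirnas={"G_target": frozenset({"miR-A", "miR-B"})},
        require_all_shared=True,
    )
    assert strict_one.empty


def test_build_snp_map_summary():
    g = disruption_graph()
    snps = snp_frame([
        ("rs1", "L1", 10, "A", "C", "TFBS", np.nan),
        ("rs2", "L1", 60, "A", "C", "TFBS", 0.9),
        ("rs3", "L1", 120, "A", "C", "lncRNA", 0.95),
    ])
    out = variants.build_snp_map(snps, g)
    assert out["fraction_with_snp"] == pytest.approx(0.5)  # L1 yes, L2 no
    assert out["class_counts"] == {"TFBS": 2, "lncRNA": 1}
    assert sum(out["class_proportions"].values()) == pytest.approx(1.0)
    assert out["per_lncrna"]["L1"]["TFBS"] == ["rs1", "rs2"]


def test_generator_events_recovered_exactly():
    """Caller output equals planted truth, with zero spurious calls."""
    for seed in (0, 1, 2):
        cfg = synth.SynthConfig(seed=seed, n_ppi_nodes=150, attach_m=2,
                                n_diabetes=40, n_dr=15, n_common=8,
                                n_lncrna=25, n_snps=60, n_planted_cliques=0)
        fx = synth.gen_snp_fixture([f"L{i:04d}" for i in range(1, 26)], cfg)
        called = []
        for _, row in fx.snps.iterrows():
            seq = fx.sequences[row["lncrna_id"]]
            if row["region_class"] == "lncRNA":
                called.extend(variants.mirna_site_call(seq, row, fx.seeds))
            elif row["region_class"] == "TFBS":
                called.extend(variants.tfbs_call(seq, row, fx.motifs))
        assert sorted(called) == sorted(fx.truth.planted_site_events)
        assert len(called) > 0


def test_fasta_and_tsv_round_trips(tmp_path):
    seqs = {"L1": "ACGT" * 30, "L2": "TTTTGGGG" * 10}
    fp = tmp_path / "t.fa"
    variants.write_fasta(seqs, str(fp))
    assert variants.read_fasta(str(fp)) == seqs

    snps = snp_frame([("rs1", "L1", 10, "A", "C", "TFBS", np.nan),
                      ("rs2", "L2", 20, "G", "T", "lncRNA", 0.91)])
    sp = tmp_path / "s.tsv"
    variants.write_snp_tsv(snps, str(sp))
    back = variants.read_snp_tsv(str(sp))
    assert back["snp_id"].tolist() == ["rs1", "rs2"]
    assert np.isnan(back["ld_r2"].iloc[0]) and back["ld_r2"].iloc[1] == 0.91

    ep = tmp_path / "e.tsv"
    variants.write_element_tsv({"miR-1": "ACGTACGT"}, str(ep), "mirna")
    assert variants.read_element_tsv(str(ep)) == {"miR-1": "ACGTACGT"}
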