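"""The generator must plant exactly the truth it reports, deterministically."""

import dataclasses
import hashlib
from collections import Counter

import numpy as np
import pytest

from netdissect import synth
from netdissect.errors import ConfigError
from netdissect.variants import seed_site


@pytest.mark.parametrize(
    "bad",
    [
        {"n_common": 500},                        # exceeds min(diabetes, dr)
        {"noise_sd": 0.0},
        {"de_fraction": 1.5},
        {"n_case": 1},
        {"attach_m": 0},
        {"cerna_density": -1.0},
        {"n_planted_cliques": 100, "clique_size_range": (50, 99),
         "n_ppi_nodes": 400},
    ],
)
def test_invalid_configs_rejected(bad):
    cfg = dataclasses.replace(
        synth.SynthConfig(n_ppi_nodes=400, n_diabetes=60, n_dr=25,
                          n_common=15, n_lncrna=20), **bad
    )
    with pytest.raises(ConfigError):
        cfg.validate()


def test_attachment_m1_yields_tree():
    cfg = synth.SynthConfig(seed=1, n_ppi_nodes=3, attach_m=1,
                            n_planted_cliques=0, n_diabetes=1, n_dr=1,
                            n_common=0, n_lncrna=1)
    g, _ = synth.gen_ppi_network(cfg)
    assert g.number_of_nodes() == 3
    assert g.number_of_edges() == 2


def test_planted_cliques_are_complete(small_cfg):
    g, truth = synth.gen_ppi_network(small_cfg)
    assert len(truth.planted_cliques) == 2
    for clique in truth.planted_cliques:
        members = sorted(clique)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                assert g.has_edge(u, v, "ppi")


def test_disease_set_counts_and_disjointness():
    cfg = synth.SynthConfig(seed=3, n_ppi_nodes=50, attach_m=1,
                            n_diabetes=4, n_dr=3, n_common=2,
                            n_lncrna=5, n_planted_cliques=0)
    g, _ = synth.gen_ppi_network(cfg)
    labels = synth.gen_disease_sets(g, cfg)
    assert Counter(labels.values()) == {"diabetes": 2, "DR": 1, "common": 2}

    cfg0 = dataclasses.replace(cfg, n_common=0)
    g0, _ = synth.gen_ppi_network(cfg0)
    labels0 = synth.gen_disease_sets(g0, cfg0)
    assert "common" not in labels0.values()
    assert Counter(labels0.values()) == {"diabetes": 4, "DR": 3}


def test_disease_set_counts_at_full_scale():
    """Default study-shaped sizes: 1,349 diabetes / 371 DR / 269 common."""
    cfg = synth.SynthConfig(seed=5)
    g, _ = synth.gen_ppi_network(cfg)
    labels = synth.gen_disease_sets(g, cfg)
    counts = Counter(labels.values())
    assert counts["common"] == 269
    assert counts["diabetes"] + counts["common"] == 1349
    assert counts["DR"] + counts["common"] == 371


def test_cerna_edges_bipartite_annotated(small_clmn, small_cfg):
    g, _ = synth.gen_ppi_network(small_cfg)
    synth.gen_disease_sets(g, small_cfg)
    cerna = synth.gen_cerna_edges(g, small_cfg)
    assert len(cerna) > 0
    assert not cerna.duplicated(subset=["lncrna", "gene"]).any()
    for row in cerna.itertuples():
        assert row.lncrna.startswith("L")
        assert not row.gene.startswith("L")
        assert len(row.shared_mirnas) >= 1


def test_cerna_density_matches_poisson_mean():
    """Mean edges per lncRNA tracks the configured Poisson rate."""
    totals = []
    for seed in range(50):
        cfg = synth.SynthConfig(seed=seed, n_ppi_nodes=300, attach_m=2,
                                n_diabetes=120, n_dr=60, n_common=30,
                                n_lncrna=100, cerna_density=1.5,
                                n_planted_cliques=0)
        g, _ = synth.gen_ppi_network(cfg)
        synth.gen_disease_sets(g, cfg)
        totals.append(len(synth.gen_cerna_edges(g, cfg)) / cfg.n_lncrna)
    mean = float(np.mean(totals))
    assert abs(mean - 1.5) / 1.5 < 0.10


def test_expression_plants_declared_shifts(small_cfg):
    cfg = dataclasses.replace(small_cfg, effect_log2fc=5.0, noise_sd=0.1,
                              de_fraction=0.2)
    genes = [f"G{i:03d}" for i in range(50)]
    m, truth = synth.gen_expression(genes, cfg)
    assert set(truth.planted_de_genes) <= set(genes)
    assert len(truth.planted_de_genes) == 10
    case, ctrl = m.samples("case"), m.samples("control")
    logm = np.log2(m.values)
    for gene, direction in truth.planted_de_genes.items():
        shift = logm.loc[gene, case].mean() - logm.loc[gene, ctrl].mean()
        assert shift == pytest.approx(5.0 * direction, abs=0.5)
    null = [g for g in genes if g not in truth.planted_de_genes]
    shifts = (logm.loc[null, case].mean(axis=1)
              - logm.loc[null, ctrl].mean(axis=1))
    assert abs(shifts.mean()) < 0.1


def test_snp_fixture_truth_verifiable_by_string_search(small_clmn, small_cfg):
    fx = synth.gen_snp_fixture(small_clmn, small_cfg)
    assert len(fx.truth.planted_site_events) > 0
    by_id = fx.snps.set_index("snp_id")
    for ev in fx.truth.planted_site_events:
        row = by_id.loc[ev.snp_id]
        seq = fx.sequences[ev.lncrna_id]
        pos = int(row["pos"])
        if ev.kind == "mirna_site":
            site = seed_site(fx.seeds[ev.element_id])
            assert row["region_class"] == "lncRNA"
        else:
            site = None
            assert row["region_class"] == "TFBS"
        carrier = row["alt"] if ev.effect == "gain" else row["ref"]
        other = row["ref"] if ev.effect == "gain" else row["alt"]
        assert ev.allele == carrier
        if site is not None:
            with_site = seq[:pos] + carrier + seq[pos + 1:]
            without = seq[:pos] + other + seq[pos + 1:]
            assert with_site[ev.start:ev.start + len(site)] == site
            assert without[ev.start:ev.start + len(site)] != site


def test_snp_fixture_ids_resolve(small_clmn, small_cfg):
    fx = synth.gen_snp_fixture(small_clmn, small_cfg)
    assert set(fx.snps["lncrna_id"]) <= set(fx.sequences)
    emitted = set(fx.snps["snp_id"])
    for ev in fx.truth.planted_site_events:
        assert ev.snp_id in emitted
        assert ev.element_id in fx.seeds or ev.element_id in fx.motifs
    r2 = fx.snps["ld_r2"]
    assert r2.dropna().between(0, 1).all()


def _fingerprint(cfg):
    g, truth = synth.gen_ppi_network(cfg)
    labels = synth.gen_disease_sets(g, cfg)
    cerna = synth.gen_cerna_edges(g, cfg)
    m, et = synth.gen_expression(sorted(labels), cfg)
    fx = synth.gen_snp_fixture(sorted(cerna["lncrna"].unique()), cfg)
    h = hashlib.sha256()
    h.update(str(sorted(g.edges())).encode())
    h.update(str(sorted(labels.items())).encode())
    h.update(cerna.to_csv().encode())
    h.update(m.values.to_csv().encode())
    h.update(str(sorted(fx.sequences.items())).encode())
    h.update(fx.snps.to_csv().encode())
    h.update(str(sorted(fx.truth.planted_site_events)).encode())
    h.update(str(sorted(et.planted_de_genes.items())).encode())
    return h.hexdigest()


def test_same_seed_same_bytes(small_cfg):
    assert _fingerprint(small_cfg) == _fingerprint(small_cfg)
    other = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
    assert _fingerprint(small_cfg) != _fingerprint(other)


def test_region_class_proportions_follow_weights():
    cfg = synth.SynthConfig(seed=2, n_ppi_nodes=200, attach_m=2,
                            n_diabetes=50, n_dr=20, n_common=10,
                            n_lncrna=600, cerna_density=0.05, n_snps=3000,
                            n_planted_cliques=0)
    fx = synth.gen_snp_fixture([f"L{i:04d}" for i in range(1, 601)], cfg)
    frac = fx.snps["region_class"].value_counts(normalize=True)
    for cls, weight in synth.REGION_WEIGHTS.items():
        assert abs(frac.get(cls, 0.0) - weight) < 0.02
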