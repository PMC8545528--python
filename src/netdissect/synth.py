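"""Synthetic study generator with planted ground truth.

Every input of the analysis — a scale-free protein-interaction backbone,
overlapping disease gene sets, bipartite lncRNA-gene ceRNA edges with
shared miRNAs, a case/control expression matrix, and SNPs with
allele-dependent binding sites planted in transcript sequences — is
generated here so each downstream stage can be tested against known
truth without any database download.

Default sizes mirror the study this package models: a ~9,064-node PPI
backbone, 1,349 diabetes / 371 retinopathy / 269 shared disease genes,
1,848 lncRNAs, and a 25-case / 5-control expression design.  All
randomness flows from the single config seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, NetdissectError, ValidationError
from .expression import ExpressionMatrix
from .graph import TypedGraph
from .variants import IUPAC, SNP_COLUMNS, SiteEvent, iupac_matches, seed_site

TRANSCRIPT_LEN = 400
BASES = "ACGT"
AMBIG = "RYSWKM"

# Sampling weights for the regulatory region catalog; most SNPs fall in
# TFBS/DHS/enhancer territory, a substantial minority in the lncRNA body.
REGION_WEIGHTS = {
    "TFBS": 0.25,
    "DHS": 0.20,
    "lncRNA": 0.20,
    "enhancer": 0.15,
    "open_chromatin": 0.10,
    "footprint": 0.05,
    "TAD": 0.05,
}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study, with study-shaped defaults."""

    seed: int = 0
    n_ppi_nodes: int = 9064
    attach_m: int = 7
    n_diabetes: int = 1349
    n_dr: int = 371
    n_common: int = 269
    n_lncrna: int = 1848
    cerna_density: float = 1.5
    n_case: int = 25
    n_control: int = 5
    de_fraction: float = 0.1
    effect_log2fc: float = 1.5
    noise_sd: float = 0.4
    n_planted_cliques: int = 3
    clique_size_range: tuple[int, int] = (8, 12)
    n_snps: int = 500

    def validate(self) -> None:
        if min(self.n_ppi_nodes, self.n_lncrna, self.n_diabetes,
               self.n_dr) <= 0:
            raise ConfigError("all entity counts must be positive")
        if self.n_common < 0 or self.n_common > min(self.n_diabetes, self.n_dr):
            raise ConfigError("n_common must satisfy 0 <= n_common <= "
                              "min(n_diabetes, n_dr)")
        if not 1 <= self.attach_m < self.n_ppi_nodes:
            raise ConfigError("attach_m must be in [1, n_ppi_nodes)")
        if self.cerna_density <= 0:
            raise ConfigError("cerna_density must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("t-testing needs >=2 samples per group")
        lo, hi = self.clique_size_range
        if self.n_planted_cliques < 0 or (self.n_planted_cliques and
                                          not 2 <= lo <= hi):
            raise ConfigError("clique_size_range must satisfy 2 <= lo <= hi")
        if self.n_planted_cliques * hi > self.n_ppi_nodes:
            raise ConfigError("planted cliques cannot exceed n_ppi_nodes")
        if self.n_snps < 0:
            raise ConfigError("n_snps must be non-negative")


@dataclass
class GroundTruth:
    """Planted truth for every generated artifact."""

    planted_de_genes: dict[str, int] = field(default_factory=dict)
    planted_cliques: list[frozenset] = field(default_factory=list)
    planted_site_events: list[SiteEvent] = field(default_factory=list)
    planted_cerna_status: list[tuple] = field(default_factory=list)
    disease_sets: dict[str, str] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        self.planted_de_genes.update(other.planted_de_genes)
        self.planted_cliques.extend(other.planted_cliques)
        self.planted_site_events.extend(other.planted_site_events)
        self.planted_cerna_status.extend(other.planted_cerna_status)
        self.disease_sets.update(other.disease_sets)
        return self

    def to_json_dict(self) -> dict:
        return {
            "planted_de_genes": dict(sorted(self.planted_de_genes.items())),
            "planted_cliques": [sorted(c) for c in self.planted_cliques],
            "planted_site_events": [
                dataclasses.asdict(e) for e in sorted(self.planted_site_events)
            ],
            "planted_cerna_status": [list(t) for t in self.planted_cerna_status],
            "disease_sets": dict(sorted(self.disease_sets.items())),
        }

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def stage_rng(seed: int, tag: str) -> np.random.Generator:
    """Independent per-stage stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(tag.encode())])
    )


def _stage_int_seed(seed: int, tag: str) -> int:
    return int(stage_rng(seed, tag).integers(0, 2**31 - 1))


def mirna_pool(cfg: SynthConfig) -> list[str]:
    n = max(10, min(400, cfg.n_lncrna // 5))
    return [f"miR-{i:04d}" for i in range(1, n + 1)]


# -- PPI backbone ------------------------------------------------------


def gen_ppi_network(cfg: SynthConfig) -> tuple[TypedGraph, GroundTruth]:
    """Preferential-attachment backbone with planted disjoint cliques.

    Growth by preferential attachment yields the long-tailed, scale-free
    degree distribution typical of interactome maps; cliques are embedded
    on disjoint random node subsets (all within-clique edges added) as
    recoverable dense-module truth.
    """
    cfg.validate()
    g_nx = nx.barabasi_albert_graph(
        cfg.n_ppi_nodes, cfg.attach_m, seed=_stage_int_seed(cfg.seed, "ppi")
    )
    names = {i: f"G{i:05d}" for i in g_nx.nodes}
    graph = TypedGraph()
    for i in sorted(g_nx.nodes):
        graph.add_node(names[i])
    for u, v in g_nx.edges:
        graph.add_edge(names[u], names[v], "ppi")

    truth = GroundTruth()
    rng = stage_rng(cfg.seed, "cliques")
    lo, hi = cfg.clique_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_planted_cliques)]
    if sum(sizes) > cfg.n_ppi_nodes:
        raise ConfigError("planted clique sizes exceed available nodes")
    # planted modules must be separated to be recoverable truth: two
    # cliques joined by a background edge form one true dense module, so
    # each subset is redrawn until it has no edge to earlier cliques
    used: set[int] = set()
    blocked: set[int] = set()  # members and neighbours of earlier cliques
    for size in sizes:
        free = [i for i in range(cfg.n_ppi_nodes) if i not in used]
        members_idx: list[int] | None = None
        for _ in range(500):
            cand = [int(i) for i in rng.choice(len(free), size=size,
                                               replace=False)]
            cand = [free[i] for i in cand]
            if not any(i in blocked for i in cand):
                members_idx = cand
                break
        if members_idx is None:
            raise ConfigError(
                "could not place separated planted cliques; "
                "reduce count or sizes"
            )
        used.update(members_idx)
        for i in members_idx:
            blocked.add(i)
            blocked.update(g_nx.neighbors(i))
        members = [names[i] for i in members_idx]
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                graph.add_edge(u, v, "ppi")
        truth.planted_cliques.append(frozenset(members))
    return graph, truth


# -- disease gene sets -------------------------------------------------


def gen_disease_sets(
    graph: TypedGraph, cfg: SynthConfig, prefer: Iterable[str] = ()
) -> dict[str, str]:
    """Label nodes diabetes / DR / common with the configured overlap.

    ``prefer`` nodes (e.g. planted-clique members, which model disease
    modules) are labeled first, then the remainder is sampled uniformly;
    labels are assigned by a random permutation so the three classes have
    exactly the configured sizes.
    """
    cfg.validate()
    candidates = sorted(n for n in graph.nodes() if graph.node_type(n) != "lncRNA")
    need = cfg.n_diabetes + cfg.n_dr - cfg.n_common
    if need > len(candidates):
        raise ConfigError(
            f"need {need} nodes for disease labels, graph has {len(candidates)}"
        )
    rng = stage_rng(cfg.seed, "disease")
    prefer = [n for n in sorted(set(prefer)) if n in set(candidates)][:need]
    rest = [n for n in candidates if n not in set(prefer)]
    extra = [rest[int(i)] for i in
             rng.choice(len(rest), size=need - len(prefer), replace=False)]
    pool = prefer + extra
    picked = [pool[int(i)] for i in rng.permutation(len(pool))]
    labels: dict[str, str] = {}
    for node in picked[:cfg.n_common]:
        labels[node] = "common"
    for node in picked[cfg.n_common:cfg.n_diabetes]:
        labels[node] = "diabetes"
    for node in picked[cfg.n_diabetes:]:
        labels[node] = "DR"
    for node, lab in labels.items():
        graph.set_type(node, lab)
    return labels


# -- ceRNA edges -------------------------------------------------------


def gen_cerna_edges(graph: TypedGraph, cfg: SynthConfig) -> pd.DataFrame:
    """Bipartite lncRNA-gene edges, each with >=1 shared miRNA.

    Edge counts per lncRNA are Poisson(cerna_density); coding partners are
    sampled uniformly from disease-labeled nodes (the ceRNA catalog the
    study used covers essentially the mapped disease genes).
    """
    cfg.validate()
    if cfg.n_lncrna <= 0:
        raise ConfigError("need at least one lncRNA")
    targets = sorted(
        n for n in graph.nodes()
        if graph.node_type(n) in ("diabetes", "DR", "common")
    )
    if not targets:
        raise ValidationError("disease labels must be assigned before "
                              "generating ceRNA edges")
    pool = mirna_pool(cfg)
    rng = stage_rng(cfg.seed, "cerna")
    rows = []
    for i in range(1, cfg.n_lncrna + 1):
        lnc = f"L{i:04d}"
        k = min(int(rng.poisson(cfg.cerna_density)), len(targets))
        if k == 0:
            continue
        partners = [targets[int(j)]
                    for j in rng.choice(len(targets), size=k, replace=False)]
        for gene in partners:
            n_shared = int(rng.integers(1, 4))
            shared = sorted(
                pool[int(j)]
                for j in rng.choice(len(pool), size=n_shared, replace=False)
            )
            rows.append((lnc, gene, shared))
    return pd.DataFrame(rows, columns=["lncrna", "gene", "shared_mirnas"])


# -- expression --------------------------------------------------------


def gen_expression(
    genes: Iterable[str], cfg: SynthConfig
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Log-normal case/control matrix with planted log2 shifts.

    Each gene has a baseline log2 abundance; planted DE genes add a
    +-effect_log2fc shift to the case group, everything gets i.i.d.
    Gaussian log2 noise.  Under this model the t-test + fold-change
    thresholds of the downstream analysis are exactly meaningful.
    """
    cfg.validate()
    genes = sorted(genes)
    rng = stage_rng(cfg.seed, "expression")
    n_genes = len(genes)
    n_de = int(round(cfg.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    directions = rng.choice([-1, 1], size=n_de)
    planted = {genes[int(i)]: int(d) for i, d in zip(de_idx, directions)}

    base = rng.uniform(3.0, 8.0, size=n_genes)
    shift = np.zeros(n_genes)
    for i, d in zip(de_idx, directions):
        shift[int(i)] = d * cfg.effect_log2fc
    samples = [f"case_{i:02d}" for i in range(1, cfg.n_case + 1)] + \
              [f"ctrl_{i:02d}" for i in range(1, cfg.n_control + 1)]
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_genes, len(samples)))
    log2 = base[:, None] + noise
    log2[:, :cfg.n_case] += shift[:, None]
    values = pd.DataFrame(np.power(2.0, log2), index=genes, columns=samples)
    groups = {s: ("case" if s.startswith("case") else "control")
              for s in samples}
    truth = GroundTruth(planted_de_genes=planted)
    return ExpressionMatrix(values, groups), truth


# -- gene sets ---------------------------------------------------------


def gen_gene_sets(
    genes: Iterable[str], cfg: SynthConfig,
    n_sets: int = 40, size_range: tuple[int, int] = (10, 80),
) -> dict[str, frozenset]:
    """Random gene-set collection (GO/pathway stand-in) over given genes."""
    genes = sorted(genes)
    rng = stage_rng(cfg.seed, "genesets")
    out: dict[str, frozenset] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(size_range[0],
                                min(size_range[1], len(genes)) + 1))
        members = frozenset(
            genes[int(j)] for j in rng.choice(len(genes), size=size,
                                              replace=False)
        )
        out[f"SET{i:03d}"] = members
    return out


# -- SNP fixture -------------------------------------------------------


@dataclass
class SnpFixture:
    """Emitted SNP table plus the sequence/element context it refers to."""

    snps: pd.DataFrame
    sequences: dict[str, str]
    seeds: dict[str, str]
    motifs: dict[str, str]
    truth: GroundTruth


def _scan_events(seq: str, pos: int, ref: str, alt: str,
                 elements: Mapping[str, str], motif_mode: bool) -> set[tuple]:
    """Independent direct string scan for allele-differential matches.

    Returns {(element_id, effect, site_start)}.  Deliberately plain loops:
    this is the generator's own verification that only planted sites
    differ between alleles, kept separate from the variant-caller
    implementation.
    """
    found: set[tuple] = set()
    for elem, pattern in elements.items():
        site = pattern if motif_mode else seed_site(pattern)
        length = len(site)
        per_allele = {}
        for allele in (ref, alt):
            s = seq[:pos] + allele + seq[pos + 1:]
            starts = set()
            for start in range(max(0, pos - length + 1),
                               min(pos, len(s) - length) + 1):
                window = s[start:start + length]
                hit = iupac_matches(window, site) if motif_mode \
                    else window == site
                if hit:
                    starts.add(start)
            per_allele[allele] = starts
        for start in per_allele[alt] - per_allele[ref]:
            found.add((elem, "gain", start))
        for start in per_allele[ref] - per_allele[alt]:
            found.add((elem, "loss", start))
    return found


def _random_motifs(rng: np.random.Generator, n: int = 4,
                   length: int = 6) -> dict[str, str]:
    """IUPAC consensus motifs with two ambiguous positions each."""
    out: dict[str, str] = {}
    while len(out) < n:
        chars = [BASES[int(rng.integers(4))] for _ in range(length)]
        for j in rng.choice(length, size=2, replace=False):
            chars[int(j)] = AMBIG[int(rng.integers(len(AMBIG)))]
        motif = "".join(chars)
        if motif not in out.values():
            out[f"TF{len(out) + 1:02d}"] = motif
    return out


def _unique_seeds(rng: np.random.Generator, mirnas: list[str]) -> dict[str, str]:
    seeds: dict[str, str] = {}
    used: set[str] = set()
    for mid in mirnas:
        while True:
            s = "".join(BASES[int(b)] for b in rng.integers(0, 4, size=8))
            # distinct 7mer-m8 sites keep planted events unambiguous
            if s[1:8] not in used:
                used.add(s[1:8])
                seeds[mid] = s
                break
    return seeds


class _Planter:
    """Plants one allele-dependent site per chosen SNP, then rejects any
    accidental allele-differential match in the scan window."""

    def __init__(self, rng: np.random.Generator, seeds: dict[str, str],
                 motifs: dict[str, str]):
        self.rng = rng
        self.seeds = seeds
        self.motifs = motifs
        self.max_len = max(
            [len(seed_site(s)) for s in seeds.values()]
            + [len(m) for m in motifs.values()]
        )

    def _clean(self, seq: list[str], pos: int, ref: str, alt: str,
               protected: set[int], expected: set[tuple]) -> bool:
        lo = max(0, pos - self.max_len + 1)
        hi = min(len(seq), pos + self.max_len)
        for _ in range(300):
            s = "".join(seq)
            got = _scan_events(s, pos, ref, alt, self.seeds, False) | \
                _scan_events(s, pos, ref, alt, self.motifs, True)
            if got == expected:
                return True
            for i in range(lo, hi):
                if i not in protected:
                    seq[i] = BASES[int(self.rng.integers(4))]
        return False

    def plant(self, seq: list[str], pos: int, element_id: str,
              kind: str, effect: str) -> tuple[str, str, int] | None:
        """Embed a site so exactly one allele completes it.

        Returns (ref, alt, site_start) or None if no clean embedding was
        found (caller retries with another element).
        """
        if not 0 <= pos < len(seq):
            raise NetdissectError(f"planted position {pos} outside sequence")
        motif_mode = kind == "tfbs"
        pattern = self.motifs[element_id] if motif_mode \
            else seed_site(self.seeds[element_id])
        length = len(pattern)
        offsets = list(self.rng.permutation(length))
        for off in offsets:
            off = int(off)
            start = pos - off
            if start < 0 or start + length > len(seq):
                continue
            if motif_mode:
                allowed = IUPAC[pattern[off].upper()]
                if len(allowed) == 4:
                    continue  # any base matches: allele cannot break it
                site_chars = [
                    IUPAC[c.upper()][int(self.rng.integers(len(IUPAC[c.upper()])))]
                    for c in pattern
                ]
                site_base = site_chars[off]
                broken = [b for b in BASES if b not in allowed]
            else:
                site_chars = list(pattern)
                site_base = pattern[off]
                broken = [b for b in BASES if b != site_base]
            other = broken[int(self.rng.integers(len(broken)))]
            ref, alt = (other, site_base) if effect == "gain" \
                else (site_base, other)
            backup = seq[start:start + length]
            seq[start:start + length] = site_chars
            seq[pos] = ref
            protected = set(range(start, start + length)) | {pos}
            if self._clean(seq, pos, ref, alt, protected,
                           {(element_id, effect, start)}):
                return ref, alt, start
            seq[start:start + length] = backup
        return None

    def neutralize(self, seq: list[str], pos: int,
                   ref: str, alt: str) -> bool:
        """Ensure an unplanted SNP produces no allele-dependent site."""
        return self._clean(seq, pos, ref, alt, {pos}, set())


def gen_snp_fixture(
    source: TypedGraph | Iterable[str], cfg: SynthConfig
) -> SnpFixture:
    """SNP table + transcript FASTA + seed/motif tables with planted events.

    ``source`` is the built network (preferred: planted losses/gains are
    then coupled to real shared-miRNA edges, yielding planted
    disrupted/created ceRNA truth) or a bare list of lncRNA ids.  Every
    lncRNA-body SNP gets a planted miRNA-site event and every TFBS-class
    SNP a planted TF-motif event; other classes stay neutral.  Rejection
    sampling guarantees no accidental allele-differential site exists in
    any caller window.
    """
    cfg.validate()
    graph = source if isinstance(source, TypedGraph) else None
    if graph is not None:
        lnc_ids = sorted(graph.nodes("lncRNA"))
    else:
        lnc_ids = sorted(str(x) for x in source)
    if not lnc_ids:
        raise ConfigError("need at least one lncRNA for the SNP fixture")

    rng = stage_rng(cfg.seed, "snps")
    pool = mirna_pool(cfg)
    extra = [f"miR-9{i:03d}" for i in range(1, 9)]
    seeds = _unique_seeds(rng, pool + extra)
    motifs = _random_motifs(rng)
    sequences = {
        lnc: ["".join(BASES[int(b)] for b in rng.integers(0, 4, size=TRANSCRIPT_LEN))]
        for lnc in lnc_ids
    }
    seq_lists = {lnc: list(s[0]) for lnc, s in sequences.items()}
    planter = _Planter(rng, seeds, motifs)

    # ceRNA context for coupling planted events to edge consequences
    edge_shared: dict[str, dict[str, set]] = {}
    gene_annot: dict[str, set] = {}
    if graph is not None:
        for u, v, _k, mirnas in graph.edges("cerna"):
            lnc, gene = (u, v) if graph.node_type(u) == "lncRNA" else (v, u)
            edge_shared.setdefault(lnc, {})[gene] = set(mirnas)
            gene_annot.setdefault(gene, set()).update(mirnas)

    classes = list(REGION_WEIGHTS)
    weights = np.array([REGION_WEIGHTS[c] for c in classes])
    weights = weights / weights.sum()

    positions: dict[str, list[int]] = {lnc: [] for lnc in lnc_ids}
    lost_by_lnc: dict[str, dict[str, set]] = {}
    gained_by_lnc: dict[str, dict[str, set]] = {}
    rows = []
    truth = GroundTruth()
    snp_no = 0
    attempts = 0
    while snp_no < cfg.n_snps and attempts < cfg.n_snps * 20:
        attempts += 1
        lnc = lnc_ids[int(rng.integers(len(lnc_ids)))]
        pos = int(rng.integers(20, TRANSCRIPT_LEN - 20))
        if any(abs(pos - p) < 40 for p in positions[lnc]):
            continue
        region = classes[int(rng.choice(len(classes), p=weights))]
        is_lead = rng.random() < 0.2
        ld_r2 = np.nan if is_lead else float(np.round(rng.uniform(0.5, 1.0), 3))
        snp_no += 1
        snp_id = f"rs{snp_no:06d}"
        seq = seq_lists[lnc]
        effect = "gain" if rng.random() < 0.5 else "loss"

        planted = None
        if region == "lncRNA":
            planted = _plant_mirna(
                planter, rng, seq, pos, lnc, effect, seeds, pool, extra,
                edge_shared, gene_annot, lost_by_lnc, gained_by_lnc,
            )
        elif region == "TFBS":
            for tf in _shuffled(rng, list(motifs)):
                res = planter.plant(seq, pos, tf, "tfbs", effect)
                if res is not None:
                    planted = (tf, "tfbs", effect, res)
                    break

        if planted is None:
            ref = BASES[int(rng.integers(4))]
            alt_choices = [b for b in BASES if b != ref]
            alt = alt_choices[int(rng.integers(3))]
            seq[pos] = ref
            if not planter.neutralize(seq, pos, ref, alt):
                snp_no -= 1
                continue
        else:
            elem, kind, eff, (ref, alt, start) = planted
            allele = alt if eff == "gain" else ref
            truth.planted_site_events.append(
                SiteEvent(snp_id, lnc, elem, kind, eff, allele, start)
            )
            if kind == "mirna_site":
                bucket = lost_by_lnc if eff == "loss" else gained_by_lnc
                bucket.setdefault(lnc, {}).setdefault(elem, set()).add(snp_id)
        positions[lnc].append(pos)
        rows.append((snp_id, lnc, pos, ref, alt, region, ld_r2))

    for lnc, seq in seq_lists.items():
        sequences[lnc] = "".join(seq)

    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    truth.planted_cerna_status = _expected_cerna_status(
        edge_shared, gene_annot, lost_by_lnc, gained_by_lnc
    )
    return SnpFixture(snps, sequences, seeds, motifs, truth)


def _shuffled(rng: np.random.Generator, items: list) -> list:
    items = sorted(items)
    return [items[int(i)] for i in rng.permutation(len(items))]


def _plant_mirna(planter, rng, seq, pos, lnc, effect, seeds, pool, extra,
                 edge_shared, gene_annot, lost_by_lnc, gained_by_lnc):
    """Pick a miRNA whose planted event has a ceRNA consequence if possible."""
    candidates: list[str] = []
    if effect == "loss":
        already = set(lost_by_lnc.get(lnc, {}))
        for gene, shared in sorted(edge_shared.get(lnc, {}).items()):
            if len(shared) == 1 and not shared & already:
                candidates.extend(sorted(shared))
    else:
        neighbors = set(edge_shared.get(lnc, {}))
        already = set(gained_by_lnc.get(lnc, {}))
        for gene, annot in sorted(gene_annot.items()):
            if gene not in neighbors:
                candidates.extend(sorted(annot - already))
    candidates = _shuffled(rng, list(dict.fromkeys(candidates)))[:3]
    candidates += _shuffled(rng, pool + extra)[:5]
    for mid in candidates:
        res = planter.plant(seq, pos, mid, "mirna_site", effect)
        if res is not None:
            return (mid, "mirna_site", effect, res)
    return None


def _expected_cerna_status(edge_shared, gene_annot, lost_by_lnc,
                           gained_by_lnc) -> list[tuple]:
    """Planted-truth disrupted/created statuses by direct set algebra."""
    out = []
    for lnc in sorted(set(lost_by_lnc) | set(gained_by_lnc)):
        lost = lost_by_lnc.get(lnc, {})
        gained = gained_by_lnc.get(lnc, {})
        for gene, shared in sorted(edge_shared.get(lnc, {}).items()):
            if shared and shared <= set(lost):
                snps = sorted({s for m in shared for s in lost[m]})
                out.append((lnc, gene, "disrupted", tuple(snps)))
        if gained:
            for gene, annot in sorted(gene_annot.items()):
                if gene in edge_shared.get(lnc, {}):
                    continue
                inter = annot & set(gained)
                if inter:
                    snps = sorted({s for m in inter for s in gained[m]})
                    out.append((lnc, gene, "created", tuple(snps)))
    return out
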