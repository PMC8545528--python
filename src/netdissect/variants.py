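"""SNP overlay on lncRNA functional geography.

Disease-associated SNPs (lead SNPs plus linkage-disequilibrium proxies
with r^2 > 0.8) are mapped onto regulatory region classes relative to
lncRNAs, and allele-dependent gain/loss of miRNA seed-match sites and of
transcription-factor consensus motifs is called by rescanning the local
sequence under each allele.  Gains and losses are then propagated to the
ceRNA layer: losing every shared miRNA site disrupts an existing
lncRNA-gene relation, while a gained site shared with a gene's annotated
miRNA set can create a new one.

A miRNA "binding site" is operationalised as an exact 7mer-m8 seed match:
the reverse complement of miRNA positions 2-8 on the transcript (6mer and
8mer modes are selectable).  TF motifs are IUPAC consensus strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import ValidationError
from .graph import TypedGraph

REGION_CLASSES = (
    "enhancer",
    "TFBS",
    "lncRNA",
    "DHS",
    "open_chromatin",
    "footprint",
    "TAD",
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SNP_COLUMNS = ["snp_id", "lncrna_id", "pos", "ref", "alt", "region_class", "ld_r2"]


@dataclass(frozen=True, order=True)
class SiteEvent:
    """An allele-dependent gain or loss of a binding element.

    ``effect="gain"`` means the site exists under the alt allele only;
    ``"loss"`` means under the ref allele only.  ``allele`` is the base
    carrying the site and ``start`` its 0-based offset in the sequence.
    """

    snp_id: str
    lncrna_id: str
    element_id: str
    kind: str  # "mirna_site" | "tfbs"
    effect: str  # "gain" | "loss"
    allele: str
    start: int


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def seed_site(seed: str, mode: str = "7mer-m8") -> str:
    """Target-site string for a miRNA seed (miRNA 5'->3', position 1 first)."""
    if mode == "7mer-m8":
        core = seed[1:8]
    elif mode == "6mer":
        core = seed[1:7]
    elif mode == "8mer":
        core = seed[0:8]
    else:
        raise ValidationError(f"unknown seed-match mode {mode!r}")
    if len(core) < (6 if mode == "6mer" else 7):
        raise ValidationError(f"seed {seed!r} too short for mode {mode!r}")
    return revcomp(core)


def _validate_motif(motif: str) -> None:
    bad = [c for c in motif.upper() if c not in IUPAC]
    if bad or not motif:
        raise ValidationError(f"invalid IUPAC motif {motif!r}")


def iupac_matches(window: str, motif: str) -> bool:
    return len(window) == len(motif) and all(
        w in IUPAC[m] for w, m in zip(window.upper(), motif.upper())
    )


def _snp_fields(snp) -> tuple[str, str, int, str, str]:
    get = snp.get if hasattr(snp, "get") else snp.__getitem__
    return (
        str(get("snp_id")),
        str(get("lncrna_id")),
        int(get("pos")),
        str(get("ref")).upper(),
        str(get("alt")).upper(),
    )


def _allele_starts(
    sequence: str, pos: int, allele: str, site_len: int, matcher
) -> set[int]:
    """Starts of matches overlapping ``pos`` with ``allele`` substituted."""
    seq = sequence[:pos] + allele + sequence[pos + 1:]
    lo = max(0, pos - site_len + 1)
    hi = min(pos, len(seq) - site_len)
    return {i for i in range(lo, hi + 1) if matcher(seq[i:i + site_len])}


def _diff_events(
    sequence: str, snp, elements: Mapping[str, str], kind: str, matcher_for
) -> list[SiteEvent]:
    snp_id, lnc, pos, ref, alt = _snp_fields(snp)
    if not 0 <= pos < len(sequence):
        raise ValidationError(
            f"SNP {snp_id} position {pos} outside sequence of length "
            f"{len(sequence)}"
        )
    if ref == alt:
        raise ValidationError(f"SNP {snp_id} has identical ref/alt alleles")
    events: list[SiteEvent] = []
    for elem_id in sorted(elements):
        site_len, matcher = matcher_for(elements[elem_id])
        ref_starts = _allele_starts(sequence, pos, ref, site_len, matcher)
        alt_starts = _allele_starts(sequence, pos, alt, site_len, matcher)
        for start in sorted(alt_starts - ref_starts):
            events.append(
                SiteEvent(snp_id, lnc, elem_id, kind, "gain", alt, start)
            )
        for start in sorted(ref_starts - alt_starts):
            events.append(
                SiteEvent(snp_id, lnc, elem_id, kind, "loss", ref, start)
            )
    return events


def mirna_site_call(
    sequence: str, snp, seeds: Mapping[str, str], mode: str = "7mer-m8"
) -> list[SiteEvent]:
    """Allele-dependent miRNA seed-site gains/losses around one SNP.

    ``seeds`` maps miRNA id -> seed-region sequence (miRNA positions 1-8,
    5'->3').  Both alleles are substituted at the SNP position and the
    surrounding window rescanned for exact seed-match sites; only sites
    overlapping the SNP can differ, so the two start sets are compared.
    """

    def matcher_for(seed: str):
        site = seed_site(seed, mode)
        return len(site), lambda w: w.upper() == site

    return _diff_events(sequence, snp, seeds, "mirna_site", matcher_for)


def tfbs_call(sequence: str, snp, motifs: Mapping[str, str]) -> list[SiteEvent]:
    """Allele-dependent TF consensus-motif gains/losses around one SNP."""

    def matcher_for(motif: str):
        _validate_motif(motif)
        return len(motif), lambda w: iupac_matches(w, motif)

    return _diff_events(sequence, snp, motifs, "tfbs", matcher_for)


def ld_filter(
    snps: pd.DataFrame, r2_threshold: float = 0.8, inclusive: bool = False
) -> pd.DataFrame:
    """Retain lead SNPs (no r^2) and LD SNPs with r^2 > threshold.

    The strict inequality mirrors the study's "r2 > 0.8" filter; pass
    ``inclusive=True`` for >=.
    """
    if snps.empty:
        return snps.copy()
    r2 = snps["ld_r2"]
    lead = r2.isna()
    keep = lead | (r2 >= r2_threshold if inclusive else r2 > r2_threshold)
    return snps[keep].copy()


def classify_regions(
    snps: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Assign every region class whose interval contains each SNP.

    ``intervals`` columns: lncrna_id, start, end, region_class with
    0-based half-open [start, end) coordinates.  A SNP may receive several
    labels (regulatory catalogs overlap); the summary counts one
    assignment per label.
    """
    bad = intervals[intervals["end"] <= intervals["start"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"malformed interval [{row['start']}, {row['end']}) for "
            f"{row['lncrna_id']}"
        )
    trees: dict[str, IntervalTree] = {}
    for _, row in intervals.iterrows():
        tree = trees.setdefault(str(row["lncrna_id"]), IntervalTree())
        tree.addi(int(row["start"]), int(row["end"]), str(row["region_class"]))
    out = snps.copy()
    labels = []
    for _, row in out.iterrows():
        tree = trees.get(str(row["lncrna_id"]))
        hits = tree[int(row["pos"])] if tree is not None else set()
        labels.append(tuple(sorted({iv.data for iv in hits})))
    out["region_classes"] = labels
    counts: dict[str, int] = {}
    for lab in labels:
        for cls in lab:
            counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    summary = {
        "assignments": total,
        "classified_snps": int(sum(bool(lab) for lab in labels)),
        "class_counts": dict(sorted(counts.items())),
        "class_proportions": {
            k: v / total for k, v in sorted(counts.items())
        } if total else {},
    }
    return out, summary


def gene_mirna_annotation(g: TypedGraph) -> dict[str, frozenset]:
    """Per coding gene, the union of miRNAs shared on its ceRNA edges."""
    annot: dict[str, set] = {}
    for u, v, _k, mirnas in g.edges("cerna"):
        gene = v if g.node_type(u) == "lncRNA" else u
        annot.setdefault(gene, set()).update(mirnas)
    return {k: frozenset(v) for k, v in annot.items()}


def cerna_disruption(
    events: Iterable[SiteEvent],
    g: TypedGraph,
    gene_mirnas: Mapping[str, frozenset] | None = None,
    require_all_shared: bool = False,
) -> pd.DataFrame:
    """ceRNA-edge consequences of miRNA-site gains/losses.

    An existing edge is ``disrupted`` when loss events remove every shared
    miRNA site on the lncRNA side; a ``created`` relation appears when a
    lncRNA gains >=1 site for a miRNA in a non-adjacent gene's annotated
    set (``require_all_shared=True`` demands the full annotated set).
    """
    events = [e for e in events if e.kind == "mirna_site"]
    for e in events:
        if not g.has_node(e.lncrna_id) or g.node_type(e.lncrna_id) != "lncRNA":
            raise ValidationError(f"event references unknown lncRNA {e.lncrna_id!r}")
    if gene_mirnas is None:
        gene_mirnas = gene_mirna_annotation(g)
    losses: dict[str, dict[str, set]] = {}
    gains: dict[str, dict[str, set]] = {}
    for e in events:
        bucket = losses if e.effect == "loss" else gains
        bucket.setdefault(e.lncrna_id, {}).setdefault(e.element_id, set()).add(
            e.snp_id
        )
    rows = []
    for lnc in sorted(set(losses) | set(gains)):
        lost = losses.get(lnc, {})
        gained = gains.get(lnc, {})
        for gene in g.neighbors(lnc, kind="cerna"):
            shared = set(g.shared_mirnas(lnc, gene))
            if shared and shared <= set(lost):
                snps = sorted({s for m in shared for s in lost[m]})
                rows.append((lnc, gene, sorted(shared), "disrupted", snps))
            else:
                rows.append((lnc, gene, sorted(shared), "unchanged", []))
        if gained:
            for gene in sorted(gene_mirnas):
                if gene == lnc or g.has_edge(lnc, gene, "cerna"):
                    continue
                annot = gene_mirnas[gene]
                inter = annot & set(gained)
                ok = annot <= set(gained) and bool(annot) if require_all_shared \
                    else bool(inter)
                if ok:
                    snps = sorted({s for m in inter for s in gained[m]})
                    rows.append((lnc, gene, sorted(inter), "created", snps))
    return pd.DataFrame(
        rows,
        columns=["lncrna", "gene", "shared_mirnas", "status", "causal_snps"],
    )


def build_snp_map(snps: pd.DataFrame, g: TypedGraph) -> dict:
    """Global lncRNA-SNP association map and per-class proportions."""
    lncrnas = sorted(g.nodes("lncRNA"))
    per_lnc: dict[str, dict[str, list[str]]] = {}
    for _, row in snps.iterrows():
        lnc = str(row["lncrna_id"])
        classes = row.get("region_classes") or (str(row["region_class"]),)
        if isinstance(classes, str):
            classes = (classes,)
        for cls in classes:
            per_lnc.setdefault(lnc, {}).setdefault(cls, []).append(
                str(row["snp_id"])
            )
    with_snp = [l for l in lncrnas if l in per_lnc]
    counts: dict[str, int] = {}
    for classes in per_lnc.values():
        for cls, ids in classes.items():
            counts[cls] = counts.get(cls, 0) + len(ids)
    total = sum(counts.values())
    return {
        "n_lncrnas": len(lncrnas),
        "n_lncrnas_with_snp": len(with_snp),
        "fraction_with_snp": len(with_snp) / len(lncrnas) if lncrnas else 0.0,
        "class_counts": dict(sorted(counts.items())),
        "class_proportions": {
            k: v / total for k, v in sorted(counts.items())
        } if total else {},
        "per_lncrna": {
            l: {c: sorted(ids) for c, ids in sorted(cls.items())}
            for l, cls in sorted(per_lnc.items())
        },
    }


# -- plain-text IO -----------------------------------------------------


def read_snp_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "lncrna_id": str})
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"SNP table missing columns {missing}")
    return df


def write_snp_tsv(snps: pd.DataFrame, path: str) -> None:
    snps.to_csv(path, sep="\t", index=False, columns=SNP_COLUMNS)


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_element_tsv(path: str) -> dict[str, str]:
    """Two-column (id, sequence-or-motif) TSV -> dict."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_element_tsv(elements: Mapping[str, str], path: str, kind: str) -> None:
    pd.DataFrame(
        sorted(elements.items()), columns=[kind, "sequence"]
    ).to_csv(path, sep="\t", index=False)
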