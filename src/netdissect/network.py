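"""Construction of the integrated ceRNA + PPI disease network.

The pipeline mirrors the construction of a comprehensive lncRNA-mRNA
network: intersect the two disease gene lists, induce the PPI subgraph on
all disease-labeled genes, keep the largest connected component, then
integrate lncRNA-gene ceRNA edges (with their shared-miRNA annotations)
on top of that backbone.  Gene-symbol matching is exact, case-sensitive
string equality; pass ``normalize=True`` to upper-case ids first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .graph import TypedGraph


@dataclass
class DropReport:
    """Identifiers excluded during mapping, for provenance."""

    genes_not_in_ppi: list[str] = field(default_factory=list)
    cerna_edges_dropped: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def intersect_gene_sets(
    diabetes: set[str], dr: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Split two disease gene lists into only/only/common parts."""
    diabetes, dr = set(diabetes), set(dr)
    common = diabetes & dr
    return diabetes - common, dr - common, common


def label_gene_sets(diabetes: set[str], dr: set[str]) -> dict[str, str]:
    d_only, dr_only, common = intersect_gene_sets(diabetes, dr)
    labels = {g: "diabetes" for g in d_only}
    labels.update({g: "DR" for g in dr_only})
    labels.update({g: "common" for g in common})
    return labels


def induce_disease_subgraph(
    ppi: TypedGraph,
    labels: dict[str, str],
    normalize: bool = False,
    report: DropReport | None = None,
) -> TypedGraph:
    """Induced PPI subgraph on disease-labeled genes present in the PPI.

    Genes absent from the PPI are dropped and recorded; an empty overlap
    yields an empty graph plus a warning, not an exception.
    """
    if report is None:
        report = DropReport()
    if normalize:
        labels = {g.upper(): t for g, t in labels.items()}
    present = {g: t for g, t in labels.items() if ppi.has_node(g)}
    report.genes_not_in_ppi = sorted(set(labels) - set(present))
    if not present:
        report.warnings.append("no disease genes found in the PPI network")
        return TypedGraph()
    sub = ppi.subgraph(present)
    for g, t in present.items():
        sub.set_type(g, t)
    return sub


def largest_component(g: TypedGraph) -> TypedGraph:
    """Connected component with the most nodes; ties go to the component
    containing the lexicographically smallest node id."""
    simple = g.simple_graph()
    if simple.number_of_nodes() == 0:
        return TypedGraph()
    components = [sorted(c) for c in nx.connected_components(simple)]
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    best = min(tied, key=lambda c: c[0])
    return g.subgraph(best)


def integrate_cerna(
    g: TypedGraph,
    cerna: pd.DataFrame,
    normalize: bool = False,
    report: DropReport | None = None,
) -> TypedGraph:
    """Add lncRNA nodes and ceRNA edges onto the gene backbone.

    ``cerna`` columns: lncrna, gene, shared_mirnas (list or comma-joined
    string).  Edges whose coding gene is absent from ``g`` are dropped and
    recorded; an edge whose "gene" is itself an lncRNA is a hard error.
    """
    if report is None:
        report = DropReport()
    out = g.copy()
    for _, row in cerna.iterrows():
        lnc, gene = str(row["lncrna"]), str(row["gene"])
        if normalize:
            gene = gene.upper()
        mirnas = row["shared_mirnas"]
        if isinstance(mirnas, str):
            mirnas = [m for m in mirnas.split(",") if m]
        if out.has_node(gene) and out.node_type(gene) == "lncRNA":
            raise ValidationError(
                f"ceRNA edge {lnc}-{gene} joins two lncRNAs"
            )
        if not out.has_node(gene):
            report.cerna_edges_dropped.append((lnc, gene))
            continue
        if not out.has_node(lnc):
            out.add_node(lnc, "lncRNA")
        elif out.node_type(lnc) != "lncRNA":
            raise ValidationError(
                f"ceRNA lncRNA id {lnc!r} collides with a {out.node_type(lnc)} node"
            )
        out.add_edge(lnc, gene, "cerna", mirnas)
    return out


def build_clmn(
    ppi: TypedGraph,
    diabetes: set[str],
    dr: set[str],
    cerna: pd.DataFrame,
    normalize: bool = False,
) -> tuple[TypedGraph, DropReport]:
    """Full construction: label -> induce -> largest component -> integrate."""
    report = DropReport()
    labels = label_gene_sets(diabetes, dr)
    sub = induce_disease_subgraph(ppi, labels, normalize=normalize,
                                  report=report)
    core = largest_component(sub)
    clmn = integrate_cerna(core, cerna, normalize=normalize, report=report)
    return clmn, report


def read_gene_list(path: str) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def read_cerna_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    need = {"lncrna", "gene", "shared_mirnas"}
    if not need <= set(df.columns):
        raise ValidationError(f"ceRNA table needs columns {sorted(need)}")
    df["shared_mirnas"] = df["shared_mirnas"].map(
        lambda s: [m for m in s.split(",") if m]
    )
    return df


def write_cerna_tsv(cerna: pd.DataFrame, path: str) -> None:
    out = cerna.copy()
    out["shared_mirnas"] = out["shared_mirnas"].map(
        lambda m: ",".join(m) if not isinstance(m, str) else m
    )
    out.to_csv(path, sep="\t", index=False)


def read_ppi_tsv(path: str) -> TypedGraph:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    g = TypedGraph()
    kind_col = "kind" if "kind" in df.columns else None
    for _, row in df.iterrows():
        kind = row[kind_col] if kind_col else "ppi"
        mirnas = [m for m in (row.get("shared_mirnas") or "").split(",") if m]
        if kind == "cerna" and not g.has_node(row["node_a"]):
            g.add_node(row["node_a"], "lncRNA")
        g.add_edge(row["node_a"], row["node_b"], kind, mirnas)
    return g
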