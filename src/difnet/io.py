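"""Plain-text readers and writers for every artifact the pipeline touches.

Formats (all tab-separated, documented in the README):

* expression matrix: header ``gene_id<TAB>sample...``, one row per gene;
* condition map: two columns ``sample_id`` / ``condition``;
* annotations: GMT (term, description, then gene ids);
* networks: commented header (condition, n_samples, node list) plus an edge
  table ``gene_a gene_b r p_value q_value sign``;
* truth manifest: ``[section]`` blocks of key/value lines.

All writers emit deterministic bytes for identical inputs; floats use
Python's shortest round-trip repr so write -> read is lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError, ParseError
from .expression import ExpressionMatrix
from .network import CoexpressionNetwork, Edge
from .quant import QpcrSample
from .simulate import PlantedTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "write_truth_manifest",
    "read_truth_manifest",
    "write_degree_table",
    "read_gene_list",
    "write_gene_list",
    "read_ct_table",
]


def _split_lines(path: Path | str) -> list[str]:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    return text.splitlines()


def _write_text(path: Path | str, text: str) -> None:
    try:
        Path(path).write_text(text)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------- expression


def write_expression(
    matrix: ExpressionMatrix, values_path, conditions_path=None
) -> None:
    lines = ["gene_id\t" + "\t".join(matrix.sample_ids)]
    for gid, row in zip(matrix.gene_ids, matrix.values.to_numpy()):
        lines.append(gid + "\t" + "\t".join(repr(float(v)) for v in row))
    _write_text(values_path, "\n".join(lines) + "\n")
    if conditions_path is not None:
        clines = ["sample_id\tcondition"]
        clines += [f"{s}\t{matrix.conditions[s]}" for s in matrix.sample_ids]
        _write_text(conditions_path, "\n".join(clines) + "\n")


def write_condition_map(conditions: Mapping[str, str], path) -> None:
    lines = ["sample_id\tcondition"]
    lines += [f"{s}\t{c}" for s, c in conditions.items()]
    _write_text(path, "\n".join(lines) + "\n")


def read_expression(values_path, conditions_path) -> ExpressionMatrix:
    lines = _split_lines(values_path)
    if not lines:
        raise ParseError(f"{values_path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{values_path}: line 1: header needs gene_id plus samples")
    samples = header[1:]
    genes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{values_path}: line {lineno}: expected {len(header)} columns, "
                f"got {len(parts)}"
            )
        genes.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{values_path}: line {lineno}: {exc}") from None
    conditions = _read_condition_map(conditions_path)
    values = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(values=values, conditions=conditions)


def _read_condition_map(path) -> dict[str, str]:
    lines = _split_lines(path)
    out: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
            )
        if lineno == 1 and parts[0] == "sample_id":
            continue
        out[parts[0]] = parts[1]
    return out


# ----------------------------------------------------------------------- GMT


def read_gmt(path, universe: Iterable[str] | None = None):
    """Read a GMT file; the universe defaults to the union of all term genes."""
    from .enrich import AnnotationMap

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(_split_lines(path), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}: line {lineno}: GMT needs term, description and >=1 gene"
            )
        tid, name, genes = parts[0], parts[1], frozenset(parts[2:])
        if tid in terms:
            raise ParseError(f"{path}: line {lineno}: duplicate term id {tid!r}")
        terms[tid] = (name, genes)
    if universe is None:
        uni = frozenset(g for _, gs in terms.values() for g in gs)
    else:
        uni = frozenset(universe)
    return AnnotationMap(terms=terms, universe=uni)


def write_gmt(annotations, path) -> None:
    lines = []
    for tid in annotations.term_ids:
        name, genes = annotations.terms[tid]
        lines.append("\t".join([tid, name, *sorted(genes)]))
    _write_text(path, "\n".join(lines) + "\n")


# ------------------------------------------------------------------ networks


def write_network(net: CoexpressionNetwork, path) -> None:
    lines = [
        f"# condition={net.condition_label}",
        f"# n_samples={net.n_samples}",
        "# nodes=" + ",".join(net.nodes),
        "gene_a\tgene_b\tr\tp_value\tq_value\tsign",
    ]
    for e in net.edges:
        lines.append(
            f"{e.gene_a}\t{e.gene_b}\t{e.r!r}\t{e.p_value!r}\t{e.q_value!r}\t{e.sign}"
        )
    _write_text(path, "\n".join(lines) + "\n")


def read_network(path) -> CoexpressionNetwork:
    lines = _split_lines(path)
    meta: dict[str, str] = {}
    body: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
        elif line.strip():
            body.append((lineno, line))
    for key in ("condition", "n_samples", "nodes"):
        if key not in meta:
            raise ParseError(f"{path}: missing '# {key}=' header line")
    edges = []
    for lineno, line in body[1:]:  # body[0] is the column header
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(
                f"{path}: line {lineno}: expected 6 columns, got {len(parts)}"
            )
        try:
            edges.append(
                Edge(
                    gene_a=parts[0],
                    gene_b=parts[1],
                    r=float(parts[2]),
                    p_value=float(parts[3]),
                    q_value=float(parts[4]),
                    sign=parts[5],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    nodes = tuple(n for n in meta["nodes"].split(",") if n)
    return CoexpressionNetwork(
        condition_label=meta["condition"],
        nodes=nodes,
        edges=tuple(edges),
        n_samples=int(meta["n_samples"]),
    )


def write_graphml(net: CoexpressionNetwork, path) -> None:
    """Optional GraphML export (XML text) via networkx."""
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


# ------------------------------------------------------------ degree tables


def write_degree_table(table: pd.DataFrame, path) -> None:
    _write_text(path, table.to_csv(sep="\t", index_label="gene_id"))


# ------------------------------------------------------------ truth manifest


def write_truth_manifest(truth: PlantedTruth, path) -> None:
    """Serialize a :class:`PlantedTruth` as sectioned key/value text."""
    lines = ["# difnet truth manifest v1"]
    lines.append("[gene_ids]")
    lines += list(truth.gene_ids)
    lines.append("[de_genes]")
    lines += [f"{g}\t{truth.de_genes[g]:+d}" for g in sorted(truth.de_genes)]
    lines.append("[modules]")
    lines += [
        f"{g}\t{truth.module_membership[g]}" for g in sorted(truth.module_membership)
    ]
    lines.append("[hubs]")
    lines += sorted(truth.hub_genes)
    for label in sorted(truth.planted_edges_by_condition):
        lines.append(f"[edges:{label}]")
        lines += [
            f"{a}\t{b}" for a, b in sorted(truth.planted_edges_by_condition[label])
        ]
    lines.append("[expected_dif_degree]")
    lines += [
        f"{g}\t{truth.expected_dif_degree[g]}" for g in sorted(truth.expected_dif_degree)
    ]
    _write_text(path, "\n".join(lines) + "\n")


def read_truth_manifest(path) -> PlantedTruth:
    gene_ids: list[str] = []
    de: dict[str, int] = {}
    modules: dict[str, str] = {}
    hubs: list[str] = []
    edges: dict[str, set[tuple[str, str]]] = {}
    expected: dict[str, int] = {}
    section = None
    for lineno, line in enumerate(_split_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section.startswith("edges:"):
                edges.setdefault(section[len("edges:"):], set())
            continue
        if section is None:
            raise ParseError(f"{path}: line {lineno}: content before any section")
        parts = line.split("\t")
        try:
            if section == "gene_ids":
                gene_ids.append(parts[0])
            elif section == "de_genes":
                de[parts[0]] = int(parts[1])
            elif section == "modules":
                modules[parts[0]] = parts[1]
            elif section == "hubs":
                hubs.append(parts[0])
            elif section.startswith("edges:"):
                edges[section[len("edges:"):]].add((parts[0], parts[1]))
            elif section == "expected_dif_degree":
                expected[parts[0]] = int(parts[1])
            else:
                raise ParseError(f"{path}: line {lineno}: unknown section {section!r}")
        except IndexError:
            raise ParseError(f"{path}: line {lineno}: too few columns") from None
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return PlantedTruth(
        gene_ids=tuple(gene_ids),
        de_genes=de,
        module_membership=modules,
        hub_genes=tuple(hubs),
        planted_edges_by_condition={k: frozenset(v) for k, v in edges.items()},
        expected_dif_degree=expected,
    )


# --------------------------------------------------------------- small files


def write_gene_list(genes: Iterable[str], path) -> None:
    _write_text(path, "\n".join(genes) + "\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in _split_lines(path) if ln.strip()]


def read_ct_table(path) -> list[QpcrSample]:
    """Parse a Ct table: columns sample, group, ct_target, ct_reference."""
    lines = _split_lines(path)
    out: list[QpcrSample] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(
                f"{path}: line {lineno}: expected 4 columns, got {len(parts)}"
            )
        if lineno == 1 and parts[0] == "sample":
            continue
        try:
            out.append(
                QpcrSample(
                    ct_target=float(parts[2]),
                    ct_reference=float(parts[3]),
                    group=parts[1],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out
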