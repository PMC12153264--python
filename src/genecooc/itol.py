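"""iToL annotation export: binary presence rings around a genome tree.

Writes iToL ``DATASET_BINARY`` flat files — one per concentric ring
(anchor-positive, partner-positive, co-localized) — and prunes a
user-supplied Newick tree down to the genomes in the collection. Tree
inference itself is out of scope; the tree is passthrough input.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Phylo

__all__ = ["write_itol_binary_dataset", "attach_tree"]

_VALID_VALUES = {1, 0, -1}


def write_itol_binary_dataset(
    labels: Sequence[str],
    indicator: Sequence[int],
    dataset_label: str,
    color: str = "#d62728",
    shape: int = 2,
    path: str | Path | None = None,
) -> str:
    """Render an iToL DATASET_BINARY ring.

    ``indicator`` holds 1 (filled symbol), 0 (empty symbol) or -1 (absent)
    per label. Labels must be unique. Returns the dataset text; also writes
    it to ``path`` when given.
    """
    if len(labels) != len(indicator):
        raise ValueError("labels and indicator must have equal length")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in iToL dataset")
    bad = [v for v in indicator if v not in _VALID_VALUES]
    if bad:
        raise ValueError(f"indicator values must be in {{1, 0, -1}}, got {bad[:5]}")

    lines = [
        "DATASET_BINARY",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{dataset_label}",
        f"COLOR,{color}",
        f"FIELD_SHAPES,{shape}",
        f"FIELD_LABELS,{dataset_label}",
        f"FIELD_COLORS,{color}",
        "DATA",
    ]
    lines.extend(f"{label},{value}" for label, value in zip(labels, indicator))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def attach_tree(newick: str, labels: Iterable[str]):
    """Validate a Newick tree against the genome set and prune extras.

    Leaves absent from ``labels`` are removed. Returns ``(tree, report)``
    where the report lists matched leaves, pruned leaves, and genomes with
    no leaf. A tree sharing no leaf with the genome set is an error.
    """
    try:
        tree = Phylo.read(io.StringIO(newick), "newick")
    except Exception as exc:
        raise ValueError(f"unparseable Newick tree: {exc}") from exc

    label_set = set(labels)
    leaf_names = [leaf.name for leaf in tree.get_terminals()]
    matched = [name for name in leaf_names if name in label_set]
    to_prune = [name for name in leaf_names if name not in label_set]
    if not matched:
        raise ValueError("tree shares no leaves with the genome set")
    for name in to_prune:
        tree.prune(next(l for l in tree.get_terminals() if l.name == name))
    report = {
        "matched": matched,
        "pruned": to_prune,
        "genomes_without_leaf": sorted(label_set - set(matched)),
    }
    return tree, report
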