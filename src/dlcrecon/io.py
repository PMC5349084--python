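"""Plain-text file formats: two-column maps, placements, valuations, and
reduction bundles.

Maps (leaf map, species map, locus map) are tab-separated two-column text,
one ``node_id<TAB>image_id`` row per node; ``#`` starts a comment.
Placements are one edge (child node id) per line.  Valuations are
``variable<TAB>true|false``.  A reduction bundle is a directory holding
``gene.nwk``, ``species.nwk``, ``leafmap.tsv``, ``params.json`` (costs,
decision parameter or budget, B, m, n, and the compiled formula, so the
instance can be rebuilt deterministically) and ``gadget_index.tsv``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

from .errors import FormatError
from .model import DuplicationPlacement, LeafMap, ReconInstance, SpeciesMap
from .reductions import (
    CNFFormula,
    DLCDPInstance,
    DLCOPInstance,
    build_apx_instance,
    build_np_instance,
)
from .trees import RootedBinaryTree, parse_newick, write_newick

PathLike = Union[str, Path]


def _data_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def read_map(path: PathLike) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for lineno, line in _data_lines(Path(path).read_text()):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        key, value = parts
        if key in out:
            raise FormatError(f"{path}:{lineno}: duplicate entry for {key!r}")
        out[key] = value
    return out


def write_map(path: PathLike, mapping: Dict[str, str], header: str = "") -> None:
    lines = [f"# {header}"] if header else []
    lines += [f"{k}\t{v}" for k, v in sorted(mapping.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_placement(path: PathLike) -> DuplicationPlacement:
    edges = []
    for _lineno, line in _data_lines(Path(path).read_text()):
        edges.append(line)
    return DuplicationPlacement(frozenset(edges))


def write_placement(path: PathLike, placement: DuplicationPlacement) -> None:
    Path(path).write_text("\n".join(sorted(placement.edges)) + "\n")


_TRUTH = {"true": True, "1": True, "t": True, "false": False, "0": False, "f": False}


def read_valuation(path: PathLike) -> Dict[int, bool]:
    out: Dict[int, bool] = {}
    for lineno, line in _data_lines(Path(path).read_text()):
        parts = line.split("\t")
        if len(parts) != 2 or parts[1].lower() not in _TRUTH:
            raise FormatError(
                f"{path}:{lineno}: expected 'variable<TAB>true|false'"
            )
        out[int(parts[0])] = _TRUTH[parts[1].lower()]
    return out


def write_valuation(path: PathLike, assignment: Dict[int, bool]) -> None:
    lines = [f"{v}\t{'true' if b else 'false'}" for v, b in sorted(assignment.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path: PathLike) -> RootedBinaryTree:
    return parse_newick(Path(path).read_text())


def write_tree(path: PathLike, tree: RootedBinaryTree) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# -- reduction bundles ---------------------------------------------------


def write_bundle(
    out_dir: PathLike, instance: Union[DLCDPInstance, DLCOPInstance]
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recon = instance.recon
    write_tree(out / "gene.nwk", recon.gene_tree)
    write_tree(out / "species.nwk", recon.species_tree)
    write_map(out / "leafmap.tsv", dict(recon.leaf_map.mapping), "gene leaf -> species leaf")
    write_map(out / "gadget_index.tsv", instance.gadget_index, "formula element -> node id")
    params = {
        "m": instance.formula.m,
        "n": instance.formula.n,
        "clauses": [list(c) for c in instance.formula.clauses],
        "cost_dup": recon.cost_dup,
        "cost_loss": recon.cost_loss,
    }
    if isinstance(instance, DLCDPInstance):
        params["mode"] = "np"
        params["decision_k"] = instance.decision_k
    else:
        params["mode"] = "apx"
        params["budget_b"] = instance.budget_b
        params["B"] = instance.B
        params["alpha"] = instance.alpha
    (out / "params.json").write_text(json.dumps(params, indent=1) + "\n")
    return out


def load_bundle(bundle_dir: PathLike) -> Union[DLCDPInstance, DLCOPInstance]:
    """Rebuild the compiled instance from a bundle and cross-check it
    against the bundled trees and leaf map."""
    bundle = Path(bundle_dir)
    try:
        params = json.loads((bundle / "params.json").read_text())
    except FileNotFoundError:
        raise FormatError(f"{bundle} is not a bundle (no params.json)") from None
    formula = CNFFormula(
        num_vars=params["m"], clauses=tuple(tuple(c) for c in params["clauses"])
    )
    if params["mode"] == "np":
        instance: Union[DLCDPInstance, DLCOPInstance] = build_np_instance(formula)
    elif params["mode"] == "apx":
        instance = build_apx_instance(formula, occurrence_bound=params.get("B"))
    else:
        raise FormatError(f"unknown bundle mode {params['mode']!r}")
    gene = read_tree(bundle / "gene.nwk")
    species = read_tree(bundle / "species.nwk")
    leafmap = read_map(bundle / "leafmap.tsv")
    recon = instance.recon
    if (
        gene != recon.gene_tree
        or species != recon.species_tree
        or leafmap != dict(recon.leaf_map.mapping)
    ):
        raise FormatError(
            f"bundle {bundle} does not match the instance rebuilt from its params"
        )
    return instance
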