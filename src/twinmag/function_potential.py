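"""KEGG-style module definitions, completion ratios, and the PBFP transform.

A module definition is an ordered list of reaction steps; a step is a
boolean expression over KO identifiers. The grammar follows KEGG module
conventions: top-level space-separated tokens are steps (all required),
commas are alternatives (OR), ``+`` joins obligatory complex subunits
(AND), spaces inside parentheses are AND, and ``-``-prefixed components
are optional and ignored. The module completion ratio (MCR) of a KO set is
the fraction of steps whose expression evaluates true.

The phylogenomically binned functional potential (PBFP) matrix is the
product A = X . C of subject-by-bin abundances X with bin-by-module MCRs
C, giving a subjects x modules profile that blends community composition
with genome functional capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ModuleDefinition",
    "ModuleParseError",
    "parse_module_definition",
    "mcr",
    "mcr_matrix",
    "pbfp",
]


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


# Expression AST: ("ko", id) | ("and", [...]) | ("or", [...]) | ("true",)


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    steps: tuple  # tuple of expression trees
    definition: str

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def kos(self) -> frozenset:
        out = set()

        def walk(node):
            if node[0] == "ko":
                out.add(node[1])
            elif node[0] in ("and", "or"):
                for child in node[1]:
                    walk(child)

        for step in self.steps:
            walk(step)
        return frozenset(out)


def _tokenize(text: str):
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "(),+ ":
            tokens.append((ch, i))
            i += 1
        elif ch == "-":
            if text[i : i + 2] == "--":
                tokens.append(("--", i))
                i += 2
            else:
                tokens.append(("-", i))
                i += 1
        else:
            j = i
            while j < len(text) and text[j] not in "(),+- ":
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


def _split_top_level(tokens, sep: str):
    """Split a token list on a separator occurring at parenthesis depth 0."""
    parts, cur, depth = [], [], 0
    for tok in tokens:
        t = tok[0]
        if t == "(":
            depth += 1
        elif t == ")":
            depth -= 1
            if depth < 0:
                raise ModuleParseError("unbalanced ')'", tok[1])
        if t == sep and depth == 0:
            parts.append(cur)
            cur = []
        else:
            cur.append(tok)
    if depth != 0:
        raise ModuleParseError("unbalanced '('", tokens[-1][1] if tokens else 0)
    parts.append(cur)
    return parts


def _parse_expr(tokens):
    """OR of AND-chains; '-'-prefixed items and '--' gaps are dropped."""
    if not tokens:
        return ("true",)
    alternatives = _split_top_level(tokens, ",")
    or_children = []
    for alt in alternatives:
        and_children = []
        skip_next = False
        for part in _split_and_units(alt):
            if part == "SKIP":
                skip_next = True
                continue
            if skip_next:
                skip_next = False
                continue
            node = _parse_unit(part)
            if node is not None:
                and_children.append(node)
        if len(and_children) == 0:
            or_children.append(("true",))
        elif len(and_children) == 1:
            or_children.append(and_children[0])
        else:
            or_children.append(("and", tuple(and_children)))
    if len(or_children) == 1:
        return or_children[0]
    return ("or", tuple(or_children))


def _split_and_units(tokens):
    """Yield token sublists joined by AND (space or '+') at depth 0; a '-'
    connective yields a SKIP marker so the following unit is ignored."""
    units, cur, depth = [], [], 0
    for tok in tokens:
        t = tok[0]
        if t == "(":
            depth += 1
            cur.append(tok)
        elif t == ")":
            depth -= 1
            cur.append(tok)
        elif depth == 0 and t in (" ", "+", "-", "--"):
            if cur:
                units.append(cur)
                cur = []
            if t in ("-", "--"):
                units.append("SKIP")
        else:
            cur.append(tok)
    if cur:
        units.append(cur)
    return units


def _parse_unit(tokens):
    if not tokens:
        return None
    if tokens[0][0] == "(":
        if tokens[-1][0] != ")":
            raise ModuleParseError("unbalanced '('", tokens[0][1])
        return _parse_expr(tokens[1:-1])
    if len(tokens) != 1:
        return _parse_expr(tokens)
    name = tokens[0][0]
    if name in (" ", ",", "+", ")", "--", "-"):
        raise ModuleParseError(f"unexpected token {name!r}", tokens[0][1])
    return ("ko", name)


def parse_module_definition(text: str, module_id: str = "") -> ModuleDefinition:
    """Parse a flat KEGG-style definition string into ordered steps."""
    if not text or not text.strip():
        raise ModuleParseError("empty module definition", 0)
    tokens = _tokenize(text.strip())
    step_token_lists = [t for t in _split_top_level(tokens, " ") if t]
    steps = tuple(_parse_expr(t) for t in step_token_lists)
    if not steps:
        raise ModuleParseError("module has no steps", 0)
    return ModuleDefinition(module_id=module_id, steps=steps, definition=text.strip())


def _evaluate(node, ko_set) -> bool:
    kind = node[0]
    if kind == "true":
        return True
    if kind == "ko":
        return node[1] in ko_set
    if kind == "and":
        return all(_evaluate(ch, ko_set) for ch in node[1])
    if kind == "or":
        return any(_evaluate(ch, ko_set) for ch in node[1])
    raise ValueError(f"unknown node kind {kind!r}")


def mcr(ko_set: Iterable[str], module: ModuleDefinition) -> float:
    """Module completion ratio: complete steps / total steps, in [0, 1]."""
    kos = set(ko_set)
    complete = sum(1 for step in module.steps if _evaluate(step, kos))
    return complete / module.n_steps


def mcr_matrix(
    ko_sets: Mapping[str, Iterable[str]] | pd.DataFrame,
    modules: Mapping[str, ModuleDefinition],
) -> pd.DataFrame:
    """Bins x modules MCR matrix C. ``ko_sets`` maps bin -> KO iterable, or
    is a 0/1 presence DataFrame (bins x KOs)."""
    if isinstance(ko_sets, pd.DataFrame):
        ko_sets = {
            bid: set(ko_sets.columns[ko_sets.loc[bid] > 0])
            for bid in ko_sets.index
        }
    return pd.DataFrame(
        {
            mid: [mcr(ko_sets[bid], mod) for bid in ko_sets]
            for mid, mod in modules.items()
        },
        index=list(ko_sets),
    )


def pbfp(X: pd.DataFrame, C: pd.DataFrame) -> pd.DataFrame:
    """PBFP transform A = X . C with label propagation.

    Columns of X (bins) must match rows of C exactly; offenders are listed
    in the error.
    """
    x_bins, c_bins = set(X.columns), set(C.index)
    if x_bins != c_bins:
        only_x = sorted(x_bins - c_bins)
        only_c = sorted(c_bins - x_bins)
        raise ValueError(
            f"bin mismatch between X and C; only in X: {only_x}, only in C: {only_c}"
        )
    C_aligned = C.loc[X.columns]
    A = X.to_numpy() @ C_aligned.to_numpy()
    return pd.DataFrame(A, index=X.index, columns=C.columns)
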