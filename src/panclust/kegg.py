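"""KEGG-style module definitions, completion ratios, and PGFC features.

A module definition is a boolean expression over KEGG ortholog (KO)
identifiers written in the KEGG convention: spaces separate reaction
steps, commas separate alternatives (OR), ``+`` joins subunits of a
complex (AND), ``-`` marks an optional component, parentheses group, and
``--`` denotes an undefined (wildcard) step.  The module completion ratio
(MCR) of a KO set is the fraction of steps whose expression is satisfied;
optional components are ignored and wildcard steps count as unsatisfied.

PhyloGenomic Functional Categories (PGFC) are amalgamated features: per
sample, SSPC counts are summed within each (SLC, KEGG module) pair, with a
companion per-cell MCR evaluated on the KOs actually detected for that SLC
in that sample.  Low-prevalence PGFCs can be filtered jointly by count and
MCR thresholds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

KO_PATTERN = re.compile(r"K\d{5}")


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


# -- expression tree --------------------------------------------------------


@dataclass(frozen=True)
class Ko:
    ko: str

    def evaluate(self, detected: frozenset[str]) -> bool:
        return self.ko in detected

    def to_text(self) -> str:
        return self.ko

    def kos(self) -> set[str]:
        return {self.ko}


@dataclass(frozen=True)
class Or:
    alternatives: tuple

    def evaluate(self, detected: frozenset[str]) -> bool:
        return any(alt.evaluate(detected) for alt in self.alternatives)

    def to_text(self) -> str:
        return ",".join(alt.to_text() for alt in self.alternatives)

    def kos(self) -> set[str]:
        return set().union(*(alt.kos() for alt in self.alternatives))


@dataclass(frozen=True)
class And:
    """Complex of required and optional components (``+`` / ``-`` chains)."""

    required: tuple
    optional: tuple = ()

    def evaluate(self, detected: frozenset[str]) -> bool:
        return all(part.evaluate(detected) for part in self.required)

    def to_text(self) -> str:
        text = "+".join(self._part_text(p) for p in self.required)
        for part in self.optional:
            text += "-" + self._part_text(part)
        return text

    @staticmethod
    def _part_text(part) -> str:
        inner = part.to_text()
        return inner if isinstance(part, Ko) else f"({inner})"

    def kos(self) -> set[str]:
        parts = self.required + self.optional
        return set().union(*(p.kos() for p in parts))


@dataclass(frozen=True)
class Wildcard:
    """An undefined step (``--``): never satisfied, contributes no KOs."""

    def evaluate(self, detected: frozenset[str]) -> bool:
        return False

    def to_text(self) -> str:
        return "--"

    def kos(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    definition_text: str
    steps: tuple = field(default=())

    def kos(self) -> set[str]:
        return set().union(set(), *(step.kos() for step in self.steps))

    def to_text(self) -> str:
        return " ".join(step.to_text() for step in self.steps)


# -- parser -----------------------------------------------------------------


class _Parser:
    """Recursive-descent parser for one space-separated step expression."""

    def __init__(self, text: str, offset: int):
        self.text = text
        self.pos = 0
        self.offset = offset  # position of this step in the full definition

    def error(self, message: str):
        raise ModuleParseError(message, self.offset + self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self):
        node = self.parse_or()
        if self.pos != len(self.text):
            self.error(f"unexpected character {self.peek()!r}")
        return node

    def parse_or(self):
        # nested OR alternatives flatten (associativity), so parsing is
        # canonical and serialization round-trips to an identical tree
        alternatives = []
        while True:
            chain = self.parse_chain()
            if isinstance(chain, Or):
                alternatives.extend(chain.alternatives)
            else:
                alternatives.append(chain)
            if self.peek() != ",":
                break
            self.pos += 1
        if len(alternatives) == 1:
            return alternatives[0]
        return Or(tuple(alternatives))

    def parse_chain(self):
        required: list = []
        optional: list = []

        def add_required(part):
            if isinstance(part, And):  # AND associativity: merge complexes
                required.extend(part.required)
                optional.extend(part.optional)
            else:
                required.append(part)

        add_required(self.parse_unit())
        while self.peek() in ("+", "-"):
            op = self.text[self.pos]
            self.pos += 1
            part = self.parse_unit()
            if op == "-":
                optional.append(part)
            else:
                add_required(part)
        if len(required) == 1 and not optional:
            return required[0]
        return And(tuple(required), tuple(optional))

    def parse_unit(self):
        ch = self.peek()
        if ch == "(":
            open_pos = self.pos
            self.pos += 1
            node = self.parse_or()
            if self.peek() != ")":
                self.pos = open_pos
                self.error("unbalanced parenthesis")
            self.pos += 1
            return node
        match = KO_PATTERN.match(self.text, self.pos)
        if match is None:
            self.error(f"expected KO identifier or '(' at {self.text[self.pos:][:8]!r}")
        self.pos = match.end()
        return Ko(match.group())


def _split_steps(text: str) -> list[tuple[str, int]]:
    """Split a definition on top-level spaces, tracking source offsets."""
    steps: list[tuple[str, int]] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ModuleParseError("unbalanced parenthesis", i)
        elif ch == " " and depth == 0:
            if i > start:
                steps.append((text[start:i], start))
            start = i + 1
    if depth != 0:
        raise ModuleParseError("unbalanced parenthesis", len(text))
    if len(text) > start:
        steps.append((text[start:], start))
    return steps


def parse_module_definition(module_id: str, definition_text: str) -> ModuleDefinition:
    """Parse a KEGG-style definition into an expression tree per step."""
    text = definition_text.strip()
    if not text:
        raise ModuleParseError("empty definition", 0)
    steps = []
    for step_text, offset in _split_steps(text):
        if step_text == "--":
            steps.append(Wildcard())
        else:
            steps.append(_Parser(step_text, offset).parse())
    return ModuleDefinition(
        module_id=module_id, definition_text=definition_text, steps=tuple(steps)
    )


def module_completion_ratio(
    module: ModuleDefinition, detected_kos: set[str] | frozenset[str]
) -> float:
    """Fraction of the module's steps satisfied by the detected KO set."""
    detected = frozenset(detected_kos)
    satisfied = sum(1 for step in module.steps if step.evaluate(detected))
    return satisfied / len(module.steps)


# -- PGFC -------------------------------------------------------------------


@dataclass
class PGFCTable:
    """Sample x (SLC, module) amalgamated counts with companion MCR matrix."""

    counts: pd.DataFrame
    mcr: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.mcr.index) or not self.counts.columns.equals(
            self.mcr.columns
        ):
            raise ValueError("counts and mcr must share index and columns")


def aggregate_pgfc(
    sspc_counts: pd.DataFrame,
    sspc_to_slc: Mapping[str, str],
    sspc_consensus_ko: Mapping[str, str],
    module_definitions: Sequence[ModuleDefinition],
) -> PGFCTable:
    """Build PGFC features from sample x SSPC counts.

    value(sample, (slc, module)) sums the sample's counts over SSPCs whose
    SLC matches and whose consensus KO occurs in the module definition; a
    KO in several modules contributes to each (amalgamations are
    unpackable, so counts are not split).  The companion MCR cell evaluates
    the module on the KOs with nonzero count in that sample restricted to
    that SLC.  SSPCs with an empty consensus KO join no module.
    """
    unknown = sorted(set(sspc_counts.columns) - set(sspc_to_slc))
    if unknown:
        raise ValueError(f"SSPCs with no SLC mapping: {unknown[:3]}")

    slcs = sorted({sspc_to_slc[s] for s in sspc_counts.columns})
    columns = pd.MultiIndex.from_tuples(
        [(slc, m.module_id) for slc in slcs for m in module_definitions],
        names=["slc", "module"],
    )
    counts = pd.DataFrame(0.0, index=sspc_counts.index, columns=columns)
    mcr = pd.DataFrame(0.0, index=sspc_counts.index, columns=columns)

    module_kos = {m.module_id: m.kos() for m in module_definitions}
    by_slc: dict[str, list[str]] = {}
    for sspc in sspc_counts.columns:
        by_slc.setdefault(sspc_to_slc[sspc], []).append(sspc)

    for slc in slcs:
        slc_sspcs = by_slc[slc]
        block = sspc_counts[slc_sspcs]
        kos = block.columns.map(lambda s: sspc_consensus_ko.get(s, ""))
        for module in module_definitions:
            in_module = kos.isin(module_kos[module.module_id] - {""})
            counts[(slc, module.module_id)] = block.loc[:, list(in_module)].sum(axis=1)
        for sample in block.index:
            detected = {
                ko for ko, n in zip(kos, block.loc[sample]) if ko and n > 0
            }
            for module in module_definitions:
                mcr.loc[sample, (slc, module.module_id)] = module_completion_ratio(
                    module, detected
                )
    return PGFCTable(counts=counts, mcr=mcr)


def filter_pgfc(
    table: PGFCTable,
    min_count: float = 0.0,
    min_mcr: float = 0.5,
    min_sample_fraction: float = 0.5,
) -> PGFCTable:
    """Drop low-prevalence PGFC columns.

    A sample passes a column when its count >= ``min_count`` and its MCR >=
    ``min_mcr``; the column is retained when the fraction of passing
    samples is at least ``min_sample_fraction``.  Retained columns are
    unchanged.
    """
    if not 0.0 <= min_mcr <= 1.0:
        raise ValueError(f"min_mcr must be in [0, 1], got {min_mcr}")
    if not 0.0 <= min_sample_fraction <= 1.0:
        raise ValueError(
            f"min_sample_fraction must be in [0, 1], got {min_sample_fraction}"
        )
    passing = (table.counts >= min_count) & (table.mcr >= min_mcr)
    keep = passing.mean(axis=0) >= min_sample_fraction
    kept = list(table.counts.columns[keep])
    return PGFCTable(counts=table.counts[kept], mcr=table.mcr[kept])
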