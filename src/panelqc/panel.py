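"""Curated gene panels and random comparator panels.

A :class:`GenePanel` is an ordered, deduplicated collection of
:class:`GeneEntry` records: a gene symbol, a stable identifier, the
functional categories the gene was curated under (immunoregulation,
chondrogenesis, ...) and two exclusion flags — overly high expression, and
no readily available PCR primers.  ``build_panel`` drops flagged entries to
produce the working panel; ``sample_random_panel`` draws a seeded uniform
random gene set of equal size from a gene universe, the comparator used to
benchmark how much discrimination the curation actually buys.

Panel tables are tab-separated UTF-8 with ``#`` comments; the ``categories``
column is ``;``-separated; flag columns accept 0/1, true/false, yes/no.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, PanelQCError
from .matrix import ExpressionMatrix

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", "", "nan", "none"}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return bool(value) and not (isinstance(value, float) and np.isnan(value))
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean flag")


@dataclass(frozen=True)
class GeneEntry:
    """One curated gene: identity, functional categories, exclusion flags."""

    symbol: str
    gene_id: str
    categories: frozenset[str] = frozenset()
    excluded_high_expression: bool = False
    excluded_no_primer: bool = False

    def __post_init__(self) -> None:
        if not self.symbol and not self.gene_id:
            raise FormatError("gene entry needs a symbol or a gene_id")

    @property
    def excluded(self) -> bool:
        return self.excluded_high_expression or self.excluded_no_primer


@dataclass
class GenePanel:
    """An ordered gene set; ``entries`` are unique by gene_id.

    ``universe_size`` records how many genes the panel was drawn or curated
    from (e.g. 25,193 annotated human genes), when known.
    """

    name: str
    entries: list[GeneEntry] = field(default_factory=list)
    universe_size: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            key = e.gene_id or e.symbol
            if key in seen:
                raise FormatError(f"duplicate gene_id in panel: {key!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_candidates(self) -> int:
        """Total entries, including flagged-for-exclusion ones."""
        return len(self.entries)

    @property
    def included(self) -> list[GeneEntry]:
        return [e for e in self.entries if not e.excluded]

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id or e.symbol for e in self.included]

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.included]


REQUIRED_COLUMNS = ("symbol", "gene_id")
OPTIONAL_COLUMNS = ("categories", "excluded_high_expression", "excluded_no_primer")


def load_panel(path, name: str | None = None) -> GenePanel:
    """Load a panel table (TSV), collapsing duplicate gene ids.

    Duplicate gene_ids (a gene curated under several functional categories)
    are merged into one entry whose categories are the union and whose flags
    are OR-ed; the first occurrence fixes the position in the panel order.
    """
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty panel table: {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"panel table missing required column(s): {missing}")
    if table.empty:
        raise FormatError(f"panel table has a header but no rows: {path}")

    merged: dict[str, dict] = {}
    order: list[str] = []
    for _, row in table.iterrows():
        symbol = str(row["symbol"]).strip() if pd.notna(row["symbol"]) else ""
        gene_id = str(row["gene_id"]).strip() if pd.notna(row["gene_id"]) else ""
        cats: set[str] = set()
        if "categories" in table.columns and pd.notna(row.get("categories")):
            cats = {c.strip() for c in str(row["categories"]).split(";") if c.strip()}
        flags = {}
        for col in ("excluded_high_expression", "excluded_no_primer"):
            flags[col] = _parse_flag(row[col]) if col in table.columns else False
        key = gene_id or symbol
        if key in merged:
            rec = merged[key]
            rec["categories"] |= cats
            rec["excluded_high_expression"] |= flags["excluded_high_expression"]
            rec["excluded_no_primer"] |= flags["excluded_no_primer"]
        else:
            merged[key] = {
                "symbol": symbol,
                "gene_id": gene_id,
                "categories": cats,
                **flags,
            }
            order.append(key)

    entries = [
        GeneEntry(
            symbol=merged[k]["symbol"],
            gene_id=merged[k]["gene_id"],
            categories=frozenset(merged[k]["categories"]),
            excluded_high_expression=merged[k]["excluded_high_expression"],
            excluded_no_primer=merged[k]["excluded_no_primer"],
        )
        for k in order
    ]
    return GenePanel(name=name or str(path), entries=entries)


def write_panel(panel: GenePanel, path) -> None:
    """Write a panel back to the TSV dialect read by :func:`load_panel`."""
    rows = [
        {
            "symbol": e.symbol,
            "gene_id": e.gene_id,
            "categories": ";".join(sorted(e.categories)),
            "excluded_high_expression": int(e.excluded_high_expression),
            "excluded_no_primer": int(e.excluded_no_primer),
        }
        for e in panel.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_panel(
    candidates: GenePanel,
    drop_high_expression: bool = True,
    drop_no_primer: bool = True,
    name: str | None = None,
) -> GenePanel:
    """Remove exclusion-flagged candidates, yielding the working panel.

    A gene flagged for both reasons is removed once and triggers a warning,
    since the two exclusion reasons are expected to be disjoint.
    """
    double = [
        e for e in candidates.entries if e.excluded_high_expression and e.excluded_no_primer
    ]
    if double and drop_high_expression and drop_no_primer:
        warnings.warn(
            f"{len(double)} gene(s) flagged for both exclusion reasons; "
            "each is removed once",
            stacklevel=2,
        )
    kept = [
        e
        for e in candidates.entries
        if not ((drop_high_expression and e.excluded_high_expression)
                or (drop_no_primer and e.excluded_no_primer))
    ]
    if not kept:
        warnings.warn("all candidate genes were excluded; panel is empty", stacklevel=2)
    return GenePanel(
        name=name or f"{candidates.name}/included",
        entries=kept,
        universe_size=candidates.universe_size,
    )


def sample_random_panel(universe, size: int, seed: int, name: str | None = None) -> GenePanel:
    """Draw ``size`` genes uniformly without replacement from ``universe``.

    The universe is deduplicated and sorted before sampling, so the result
    depends only on its membership (not on file order) and on the seed.
    """
    ids = sorted(set(str(g) for g in universe))
    if size > len(ids):
        raise ValueError(f"requested {size} genes from a universe of {len(ids)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=size, replace=False)
    entries = [GeneEntry(symbol=ids[i], gene_id=ids[i]) for i in sorted(chosen)]
    return GenePanel(
        name=name or f"random-{size}-seed{seed}",
        entries=entries,
        universe_size=len(ids),
    )


def subset_matrix(matrix: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Restrict a matrix to the panel's included genes, in panel order.

    Genes are resolved by gene_id first, then by case-insensitive symbol.
    Panel genes absent from the matrix are skipped and counted in
    ``attrs['n_panel_missing']``; zero overlap is an error (almost always an
    identifier-scheme mismatch).
    """
    exact = {str(g): str(g) for g in matrix.values.index}
    folded: dict[str, str] = {}
    for g in matrix.values.index:
        folded.setdefault(str(g).casefold(), str(g))

    rows: list[str] = []
    seen: set[str] = set()
    missing = 0
    for entry in panel.included:
        label = None
        if entry.gene_id and entry.gene_id in exact:
            label = entry.gene_id
        elif entry.symbol and entry.symbol.casefold() in folded:
            label = folded[entry.symbol.casefold()]
        if label is None:
            missing += 1
        elif label not in seen:
            rows.append(label)
            seen.add(label)
    if not rows:
        raise PanelQCError(
            f"no overlap between panel {panel.name!r} and matrix gene identifiers"
        )
    out = matrix.replace(values=matrix.values.loc[rows])
    out.attrs["panel_name"] = panel.name
    out.attrs["n_panel_missing"] = missing
    if matrix.gene_lengths is not None:
        out.gene_lengths = matrix.gene_lengths.reindex(rows)
    return out
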