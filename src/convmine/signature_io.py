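"""Reading, validating, normalizing and writing protein-signature collections.

Two container types are defined here and used throughout the package:

``SignatureSet``
    An ordered mapping of category labels (a disease, an aging mechanism, a
    drug response, ...) to ordered, de-duplicated lists of uppercase protein
    symbols.

``GeneSetLibrary``
    GMT-style term → member-set mapping over a declared symbol universe, the
    input of over-representation analysis.

Symbols are matched by exact string after whitespace-strip and uppercasing;
no alias or ortholog resolution is attempted. An optional user-supplied
two-column alias map (old → new) can be applied before de-duplication.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidSymbolError",
    "SignatureSet",
    "GeneSetLibrary",
    "normalize_symbol",
    "read_alias_map",
    "read_signatures",
    "read_symbol_list",
    "read_library",
    "write_signatures",
    "write_library",
]

SIGNATURE_FORMATS = ("tsv", "gmt", "list")


class InvalidSymbolError(ValueError):
    """A token normalized to the empty string."""


def normalize_symbol(raw: str) -> str:
    """Strip surrounding whitespace and uppercase a symbol token.

    Raises
    ------
    InvalidSymbolError
        If the token is empty after normalization.
    """
    symbol = raw.strip().upper()
    if not symbol:
        raise InvalidSymbolError(f"symbol {raw!r} is empty after normalization")
    return symbol


@dataclass
class SignatureSet:
    """Named collection of protein signatures, one list per category.

    Category labels are case-sensitive and preserved verbatim; insertion
    order is the file order and is stable across reads of the same file.
    Within a category, symbols are unique and stored in first-seen order.
    """

    name: str
    categories: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for label, symbols in self.categories.items():
            if len(set(symbols)) != len(symbols):
                raise ValueError(f"category {label!r} contains duplicate symbols")
            if any(not s for s in symbols):
                raise InvalidSymbolError(f"category {label!r} contains an empty symbol")

    @classmethod
    def from_tokens(
        cls,
        name: str,
        categories: Mapping[str, Sequence[str]],
        provenance: str = "",
        alias: Mapping[str, str] | None = None,
    ) -> "SignatureSet":
        """Build a SignatureSet from raw tokens: normalize, alias-map, dedup.

        Duplicates within a category are dropped with a logged warning,
        keeping the first occurrence. A category with zero symbols is an
        error.
        """
        clean: dict[str, list[str]] = {}
        for label, tokens in categories.items():
            seen: dict[str, None] = {}
            n_dup = 0
            for tok in tokens:
                sym = normalize_symbol(tok)
                if alias:
                    sym = alias.get(sym, sym)
                if sym in seen:
                    n_dup += 1
                else:
                    seen[sym] = None
            if not seen:
                raise ValueError(f"category {label!r} has zero symbols")
            if n_dup:
                logger.warning(
                    "category %r: dropped %d duplicate symbol(s)", label, n_dup
                )
            clean[label] = list(seen)
        if not clean:
            raise ValueError("signature set has no categories")
        return cls(name=name, categories=clean, provenance=provenance)

    @property
    def labels(self) -> list[str]:
        return list(self.categories)

    def all_symbols(self) -> set[str]:
        """Union of symbols over all categories."""
        out: set[str] = set()
        for symbols in self.categories.values():
            out.update(symbols)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureSet):
            return NotImplemented
        return self.categories == other.categories

    def __len__(self) -> int:
        return len(self.categories)


@dataclass
class GeneSetLibrary:
    """GMT-semantics gene-set library: term → member set over a universe.

    Every term member lies in the universe; empty terms are rejected. When
    no universe is declared it defaults to the union of all members.
    """

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        for label, members in self.terms.items():
            if not members:
                raise ValueError(f"term {label!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"term {label!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.terms)


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV old → new symbol alias map."""
    alias: dict[str, str] = {}
    for fields in _rows(path, n_min=2):
        alias[normalize_symbol(fields[0])] = normalize_symbol(fields[1])
    return alias


def _rows(path: str | Path, n_min: int) -> Iterable[list[str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_min:
                raise ValueError(f"{path}:{lineno}: expected ≥{n_min} tab-separated fields")
            yield fields


def read_signatures(
    path: str | Path,
    format: str = "tsv",
    name: str | None = None,
    alias: Mapping[str, str] | None = None,
) -> SignatureSet:
    """Read a signature collection.

    Supported dialects:

    - ``tsv``: two columns per row, ``category<TAB>symbol``.
    - ``gmt``: one category per line, ``label<TAB>description<TAB>members...``.
    - ``list``: one symbol per line; the file stem becomes the single
      category label. A directory may be given, yielding one category per
      ``*.txt`` file in sorted order.

    Lines starting with ``#`` and blank lines are ignored everywhere.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    raw: dict[str, list[str]] = {}
    if format == "tsv":
        for fields in _rows(path, n_min=2):
            raw.setdefault(fields[0], []).append(fields[1])
    elif format == "gmt":
        for fields in _rows(path, n_min=3):
            raw[fields[0]] = fields[2:]
    elif format == "list":
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        if not files:
            raise ValueError(f"no *.txt signature files under {path}")
        for file in files:
            raw[file.stem] = [f[0] for f in _rows(file, n_min=1)]
    else:
        raise ValueError(f"unknown signature format {format!r}; use one of {SIGNATURE_FORMATS}")
    if not raw:
        raise ValueError(f"{path}: no signature rows found")
    return SignatureSet.from_tokens(name, raw, provenance=str(path), alias=alias)


def read_symbol_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line file into an ordered de-duplicated list."""
    seen: dict[str, None] = {}
    for fields in _rows(path, n_min=1):
        seen.setdefault(normalize_symbol(fields[0]), None)
    if not seen:
        raise ValueError(f"{path}: empty symbol list")
    return list(seen)


def read_library(
    path: str | Path,
    universe: set[str] | None = None,
    on_stray: str = "drop",
) -> GeneSetLibrary:
    """Read a GMT file into a :class:`GeneSetLibrary`.

    Parameters
    ----------
    universe
        Declared background set. Defaults to the union of all members.
    on_stray
        What to do with members outside a supplied universe: ``"drop"``
        removes them with a warning, ``"error"`` raises.
    """
    if on_stray not in ("drop", "error"):
        raise ValueError("on_stray must be 'drop' or 'error'")
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for fields in _rows(path, n_min=3):
        label = fields[0]
        members = {normalize_symbol(tok) for tok in fields[2:] if tok.strip()}
        if universe is not None:
            stray = members - universe
            if stray:
                if on_stray == "error":
                    raise ValueError(f"term {label!r}: members outside universe: {sorted(stray)[:5]}")
                logger.warning("term %r: dropped %d member(s) outside universe", label, len(stray))
                members -= stray
        if not members:
            raise ValueError(f"term {label!r} has no members (after universe filtering)")
        terms[label] = members
        descriptions[label] = fields[1]
    if not terms:
        raise ValueError(f"{path}: GMT file contains no terms")
    return GeneSetLibrary(
        terms=terms,
        universe=set(universe) if universe is not None else set(),
        descriptions=descriptions,
    )


def write_signatures(sigs: SignatureSet, path: str | Path, format: str = "tsv") -> None:
    """Write a SignatureSet; ``read(write(S, f), f) == S`` for every format."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as handle:
            for label, symbols in sigs.categories.items():
                for sym in symbols:
                    handle.write(f"{label}\t{sym}\n")
    elif format == "gmt":
        with open(path, "w", encoding="utf-8") as handle:
            for label, symbols in sigs.categories.items():
                handle.write("\t".join([label, sigs.provenance or "-", *symbols]) + "\n")
    elif format == "list":
        path.mkdir(parents=True, exist_ok=True)
        for label, symbols in sigs.categories.items():
            with open(path / f"{label}.txt", "w", encoding="utf-8") as handle:
                handle.write("\n".join(symbols) + "\n")
    else:
        raise ValueError(f"unknown signature format {format!r}; use one of {SIGNATURE_FORMATS}")


def write_library(lib: GeneSetLibrary, path: str | Path) -> None:
    """Write a GeneSetLibrary as GMT (members sorted for stable output)."""
    with open(path, "w", encoding="utf-8") as handle:
        for label, members in lib.terms.items():
            desc = lib.descriptions.get(label, "-") or "-"
            handle.write("\t".join([label, desc, *sorted(members)]) + "\n")
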