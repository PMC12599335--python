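"""Packaged keyword vocabularies for product-string matching.

Both tables are plain TSV and user-replaceable: the role vocabulary maps
annotation keywords to functional roles (first matching row wins, so more
specific patterns come first), and the MGE vocabulary maps keywords to
mobile-genetic-element categories.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

# roles mapped onto the RoleCall vocabulary; the eps_conserved/eps_terminal
# vocabulary rows exist to anchor eps locus detection and fold into the
# regulator role for per-gene calls
ROLE_ALIASES = {"eps_conserved": "regulator", "eps_terminal": "regulator"}


@dataclass(frozen=True)
class VocabEntry:
    role: str
    kind: str  # cwps | eps | any
    anchor: bool
    pattern: re.Pattern

    @property
    def call_role(self) -> str:
        return ROLE_ALIASES.get(self.role, self.role)


def _load_tsv(path: Path | None, package_name: str) -> list[dict]:
    if path is not None:
        with open(path) as fh:
            return list(csv.DictReader(fh, delimiter="\t"))
    text = resources.files("pellicle.data").joinpath(package_name).read_text()
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


@lru_cache(maxsize=4)
def _role_vocab_cached(path_str: str | None) -> tuple[VocabEntry, ...]:
    rows = _load_tsv(Path(path_str) if path_str else None, "role_keywords.tsv")
    return tuple(
        VocabEntry(
            role=r["role"], kind=r["kind"], anchor=r["anchor"] == "1",
            pattern=re.compile(r["pattern"], re.IGNORECASE),
        )
        for r in rows
    )


def role_vocabulary(path: str | Path | None = None) -> tuple[VocabEntry, ...]:
    return _role_vocab_cached(str(path) if path else None)


@lru_cache(maxsize=4)
def _mge_vocab_cached(path_str: str | None) -> tuple[tuple[str, re.Pattern], ...]:
    rows = _load_tsv(Path(path_str) if path_str else None, "mge_keywords.tsv")
    return tuple((r["category"], re.compile(r["pattern"], re.IGNORECASE)) for r in rows)


def mge_vocabulary(path: str | Path | None = None) -> tuple[tuple[str, re.Pattern], ...]:
    return _mge_vocab_cached(str(path) if path else None)


def match_roles(product: str, kind: str,
                vocab: tuple[VocabEntry, ...] | None = None) -> list[VocabEntry]:
    """All vocabulary rows of the given kind (or 'any') matching a product."""
    vocab = vocab or role_vocabulary()
    return [
        e for e in vocab
        if e.kind in (kind, "any") and e.pattern.search(product)
    ]


def first_role(product: str, kind: str,
               vocab: tuple[VocabEntry, ...] | None = None) -> str | None:
    """Role of the first matching vocabulary row (file order = priority)."""
    hits = match_roles(product, kind, vocab)
    return hits[0].call_role if hits else None


def is_hypothetical(product: str) -> bool:
    p = product.lower()
    return "hypothetical" in p or "uncharacterized" in p or p in ("", "protein")


def mge_categories(product: str,
                   vocab: tuple[tuple[str, re.Pattern], ...] | None = None) -> list[str]:
    vocab = vocab or mge_vocabulary()
    return [cat for cat, pat in vocab if pat.search(product)]
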