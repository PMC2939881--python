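"""Text normalization primitives shared by the corpus model and the engine.

Tokenization is deliberately simple and order-free friendly: case-folded,
punctuation-stripped, whitespace-split, with a fixed English stopword list
removed. Numbers are retained (they carry signal in methods sections).
The stopword list is frozen so that scans are reproducible across runs.
"""

from __future__ import annotations

import re
import unicodedata
from typing import NamedTuple

# Fixed 127-word English stopword list (function words only; no domain terms).
STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are as at be
    because been before being below between both but by can cannot could did
    do does doing down during each few for from further had has have having
    he her here hers herself him himself his how i if in into is it its
    itself just me more most my myself no nor not now of off
    on once only or other our ours ourselves out over own same she
    should so some such than that the their theirs them themselves then there
    these they this those through to too under until up very was we were
    what when where which while who whom why will with would you your yours
    yourself yourselves
    """.split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Normalize ``text`` to a list of non-stopword tokens.

    Case-folds, strips punctuation (any non-alphanumeric character acts as a
    separator), splits on the resulting boundaries and removes stopwords.
    Total on any string; the empty string yields an empty list.
    """
    return [t for t in _TOKEN_RE.findall(text.casefold()) if t not in STOPWORDS]


def strip_diacritics(s: str) -> str:
    """Remove combining marks: 'García' -> 'Garcia'."""
    return "".join(
        c for c in unicodedata.normalize("NFKD", s) if not unicodedata.combining(c)
    )


class AuthorKey(NamedTuple):
    """Normalized author identity: case-folded, diacritic-free surname plus
    first initial. Two keys compare equal iff both fields are equal — the
    loosest rule that still avoids trivial string-mismatch misses."""

    surname: str
    initial: str


def author_key(name: str) -> AuthorKey | None:
    """Normalize one author name to an :class:`AuthorKey`.

    Accepts "Surname, Given Names" (preferred) or "Given Surname"; returns
    ``None`` when no usable surname can be extracted.
    """
    name = strip_diacritics(name).strip()
    if not name:
        return None
    if "," in name:
        surname, _, given = name.partition(",")
    else:
        parts = name.split()
        if len(parts) == 1:
            surname, given = parts[0], ""
        else:
            surname, given = parts[-1], " ".join(parts[:-1])
    surname = re.sub(r"[^a-z]", "", surname.casefold())
    given = given.strip()
    initial = ""
    for ch in given:
        if ch.isalpha():
            initial = ch.casefold()
            break
    if not surname:
        return None
    return AuthorKey(surname, initial)
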