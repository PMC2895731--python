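"""Label normalization and whitespace-delimited containment.

Category labels from different ontologies only match lexically after they are
brought onto a common form: lowercased, split into word tokens (hyphens count
as separators, edge punctuation is stripped) and each token reduced to its
English singular.  Singularization is rule-based — an explicit table of
irregular plurals, a table of invariant words, then ordered suffix rules —
rather than a statistical stemmer, so every mapping is auditable and the
tables can be replaced wholesale.

"delimited by whitespaces" containment is decided on the normalized token
lists: the needle's tokens must occur as a contiguous run of the haystack's
tokens, which is the faithful token-level reading of substring-with-word-
boundaries once both sides have been normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

_EDGE_PUNCT = ".,;:()[]{}\"'?&/"
_WS_SPLIT = re.compile(r"[\s\-]+")


def _read_pairs(text: str) -> dict[str, str]:
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        plural, _, singular = line.partition("\t")
        table[plural.strip()] = singular.strip()
    return table


def _read_words(text: str) -> frozenset[str]:
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_tables(
    irregulars_path: str | Path | None = None,
    invariants_path: str | Path | None = None,
) -> tuple[dict[str, str], frozenset[str]]:
    """Load the (irregular plural -> singular) and invariant-word tables.

    Without arguments, the tables shipped with the package are used; paths
    point at replacement files in the same one-entry-per-line format.
    """
    if irregulars_path is None:
        text = resources.files("anatfunc.data").joinpath(
            "irregular_plurals.txt").read_text()
    else:
        text = Path(irregulars_path).read_text()
    irregulars = _read_pairs(text)
    if invariants_path is None:
        text = resources.files("anatfunc.data").joinpath(
            "invariant_words.txt").read_text()
    else:
        text = Path(invariants_path).read_text()
    invariants = _read_words(text)
    return irregulars, invariants


_IRREGULARS, _INVARIANTS = load_tables()


def singularize(
    word: str,
    irregulars: dict[str, str] | None = None,
    invariants: frozenset[str] | None = None,
) -> str:
    """Return the English singular of a single lowercase word token.

    Rules are applied in order: irregulars table, invariant words, -ies -> -y,
    sibilant -es endings (-sses/-uses/-xes/-ches/-shes strip the "es", a
    single -ses/-zes strips only the "s", so "glasses" -> "glass" but
    "noses" -> "nose"), and finally a trailing -s strip that leaves -ss, -us,
    -is and bare "s" alone.  Total on any token; words already singular come
    back unchanged.
    """
    irr = _IRREGULARS if irregulars is None else irregulars
    inv = _INVARIANTS if invariants is None else invariants
    if word in irr:
        return irr[word]
    if word in inv:
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("sses", "uses", "xes", "ches", "shes")):
        return word[:-2]
    if word.endswith(("ses", "zes")):
        return word[:-1]
    if (
        word.endswith("s")
        and len(word) > 2
        and not word.endswith(("ss", "us", "is", "'s"))
    ):
        return word[:-1]
    return word


@dataclass(frozen=True)
class NormalizedLabel:
    """A label reduced to lowercase singular word tokens."""

    tokens: tuple[str, ...]
    source: str

    @property
    def joined(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __bool__(self) -> bool:
        return bool(self.tokens)


def tokenize(label: str) -> list[str]:
    """Split on whitespace and hyphens, lowercase, strip edge punctuation."""
    out = []
    for raw in _WS_SPLIT.split(label.lower()):
        token = raw.strip(_EDGE_PUNCT)
        if token:
            out.append(token)
    return out


def normalize_label(label: str) -> NormalizedLabel:
    """Normalize a category label to its token form.

    Idempotent: normalizing the joined token text of a normalized label
    reproduces the same tokens.
    """
    return NormalizedLabel(
        tokens=tuple(singularize(token) for token in tokenize(label)),
        source=label,
    )


def contains_delimited(haystack: NormalizedLabel, needle: NormalizedLabel) -> bool:
    """True iff needle's tokens occur contiguously within haystack's tokens.

    The empty needle matches nothing.  This is the whitespace-delimited
    substring test lifted to normalized token sequences: "ear" is contained
    in "abnormality of the ears", but not in "heart".
    """
    n, h = needle.tokens, haystack.tokens
    if not n or len(n) > len(h):
        return False
    return any(h[i:i + len(n)] == n for i in range(len(h) - len(n) + 1))


# ---------------------------------------------------------------------------
# pluralization (used by the fixture generator, inverse of singularize on the
# vocabulary it is applied to)

_PLURAL_IRREGULARS = {v: k for k, v in _IRREGULARS.items()}
_VOWELS = "aeiou"


def pluralize(word: str) -> str:
    """Best-effort English plural; exact inverse of singularize on words
    covered by the shipped tables and the regular suffix rules."""
    if word in _INVARIANTS:
        return word
    if word in _PLURAL_IRREGULARS:
        return _PLURAL_IRREGULARS[word]
    if word.endswith(("ss", "x", "ch", "sh")):
        return word + "es"
    if word.endswith("s"):
        # -us/-is and other s-final singulars without a listed irregular
        # plural are used unchanged
        return word
    if word.endswith("y") and len(word) > 1 and word[-2] not in _VOWELS:
        return word[:-1] + "ies"
    return word + "s"
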