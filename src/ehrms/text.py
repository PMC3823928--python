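"""Dictionary-based clinical concept extraction with negation detection.

A lightweight, NegEx-style stand-in for a full clinical NLP system:
surface forms from a curated term dictionary are matched against
tokenized note text (longest match first, left to right, each token
consumed once), and a match is counted as *negative* when a negation cue
occurs within a fixed token window before the match start in the same
sentence (sentences delimited by periods/semicolons).  No stemming or
terminology lookup is attempted — the dictionary lists surface variants
explicitly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

from .records import ValidationError

_TOKEN_RE = re.compile(r"[a-z0-9']+")
_SENTENCE_RE = re.compile(r"[.;]")

DEFAULT_NEGATION_CUES = ["no", "denies", "without", "not"]


@dataclass
class TermDictionary:
    """Maps variable names to lowercase surface forms, plus negation cues."""
    terms: dict[str, list[str]]
    negation_cues: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATION_CUES))
    negation_window: int = 6

    def __post_init__(self):
        if self.negation_window < 1:
            raise ValidationError("negation_window must be >= 1")
        for var, forms in self.terms.items():
            if not forms:
                raise ValidationError(f"variable {var!r} has no surface forms")
            for f in forms:
                if f != f.lower():
                    raise ValidationError(f"surface form {f!r} must be lowercase")

    @classmethod
    def from_csv(cls, terms_path, cues_path=None, negation_window: int = 6) -> "TermDictionary":
        """Two-column CSV (variable, surface form) plus optional cue list file."""
        terms: dict[str, list[str]] = {}
        with open(terms_path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                var, form = row[0].strip(), row[1].strip().lower()
                terms.setdefault(var, []).append(form)
        cues = list(DEFAULT_NEGATION_CUES)
        if cues_path is not None:
            with open(cues_path, encoding="utf-8") as fh:
                cues = [line.strip().lower() for line in fh if line.strip()]
        return cls(terms=terms, negation_cues=cues, negation_window=negation_window)

    def to_csv(self, terms_path) -> None:
        with open(terms_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            for var, forms in self.terms.items():
                for f in forms:
                    w.writerow([var, f])


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def extract_mentions(note: str, dictionary: TermDictionary) -> dict[str, tuple[int, int]]:
    """Count (positive, negative) mentions of each dictionary variable.

    Empty notes yield all-zero counts. Output is invariant to case and to
    runs of whitespace, and concatenating notes sums their counts when no
    match or cue spans the junction.
    """
    counts = {var: [0, 0] for var in dictionary.terms}
    # surface forms as token tuples, longest first for greedy matching
    patterns: list[tuple[tuple[str, ...], str]] = []
    for var, forms in dictionary.terms.items():
        for form in forms:
            toks = tuple(_tokenize(form))
            if toks:
                patterns.append((toks, var))
    patterns.sort(key=lambda p: len(p[0]), reverse=True)
    cue_patterns = [tuple(_tokenize(c)) for c in dictionary.negation_cues]
    cue_patterns = [c for c in cue_patterns if c]
    window = dictionary.negation_window

    for sentence in _SENTENCE_RE.split(note):
        tokens = _tokenize(sentence)
        i = 0
        while i < len(tokens):
            matched = False
            for toks, var in patterns:
                if tuple(tokens[i:i + len(toks)]) == toks:
                    lo = max(0, i - window)
                    negated = any(
                        tuple(tokens[j:j + len(c)]) == c
                        for c in cue_patterns
                        for j in range(lo, i)
                    )
                    counts[var][1 if negated else 0] += 1
                    i += len(toks)
                    matched = True
                    break
            if not matched:
                i += 1
    return {var: (p, n) for var, (p, n) in counts.items()}


def default_term_dictionary() -> TermDictionary:
    """Toy MS-relevant dictionary matching the generator's narrative variables."""
    return TermDictionary(terms={
        "demyelination": ["demyelination", "demyelinating lesion", "demyelinating lesions"],
        "optic_neuritis": ["optic neuritis"],
        "gait_difficulty": ["gait difficulty", "gait instability", "difficulty walking"],
        "paresthesia": ["paresthesia", "paresthesias", "numbness and tingling"],
        "spasticity": ["spasticity", "muscle spasticity"],
        "interferon": ["interferon", "interferon beta"],
    })
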