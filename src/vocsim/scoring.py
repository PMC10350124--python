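"""Automated intelligibility scoring of recognizer output against transcripts.

Two graders, mirroring how clinical speech tests are scored:

* **Sentence scoring** — per sentence, the number of words common to the
  recognizer result and the transcript, order ignored ("Skipped Abbey
  rocks" vs "Abbey skipped rocks" scores 3). Common words are counted as a
  multiset intersection, so repeated words only credit up to their
  transcript count. Totals are pooled over the sentence set.

* **Word-list scoring** — word-by-word positional comparison. Recognizer
  output for a word list may have extra or missing words (a missed word, or
  one word heard as two), so the lists are first equalized by a greedy
  search: repeatedly trial-delete each single word from the longer list,
  keep the deletion that maximizes the positional similarity of what
  remains, until lengths match; the resulting positional match count is the
  score. A brute-force enumerator over all deletion sets is provided as an
  exact reference for small instances.

Matching is by spelling, optionally homophone-aware through a
grapheme-to-phoneme backend ("whine" ≡ "wine").
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .phonetics import builtin_lexicon_g2p, strip_stress

logger = logging.getLogger(__name__)

#: A backend maps a cleaned token to a phoneme sequence, or None if unknown.
G2PBackend = Callable[[str], Optional[Sequence[str]]]
#: A matcher decides whether two cleaned tokens count as the same word.
Matcher = Callable[[str, str], bool]

_TOKEN_OK = re.compile(r"^[^\sA-Z]+$")
_STRIP = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


class WordSequence(tuple):
    """An ordered sequence of cleaned tokens (lower-case, punctuation-free)."""

    def __new__(cls, words: Iterable[str]) -> "WordSequence":
        toks = tuple(words)
        for w in toks:
            if not w:
                raise ValueError("word sequences cannot contain empty tokens")
            if not _TOKEN_OK.match(w) or _STRIP.search(w):
                raise ValueError(
                    f"token {w!r} is not cleaned (upper-case or punctuation); "
                    "pass raw text through clean_text first"
                )
        return super().__new__(cls, toks)


@dataclass(frozen=True)
class ScoreResult:
    """Correct-word count out of a total, with the derived percentage."""

    n_correct: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_total):
            raise ValueError(
                f"need 0 <= n_correct <= n_total; got {self.n_correct}/{self.n_total}"
            )

    @property
    def percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_correct / self.n_total

    def __add__(self, other: "ScoreResult") -> "ScoreResult":
        return ScoreResult(self.n_correct + other.n_correct,
                           self.n_total + other.n_total)


def clean_text(text: str) -> WordSequence:
    """Lower-case, strip all punctuation (apostrophes and hyphens included),
    and split on whitespace. ``"Don't stop!"`` → ``(dont, stop)``."""
    stripped = _STRIP.sub("", text.lower())
    return WordSequence(stripped.split())


def words_match(a: str, b: str, phonetic: G2PBackend | None = None) -> bool:
    """True if two cleaned tokens are the same word.

    Identical spellings always match. With a grapheme-to-phoneme backend,
    differently-spelled tokens also match when their phoneme sequences are
    identical after stress-marker removal (homophones). A backend failure
    on either token falls back to spelling comparison with a warning.
    """
    if a == b:
        return True
    if phonetic is None:
        return False
    try:
        pa, pb = phonetic(a), phonetic(b)
    except Exception:  # backend crash must not sink a scoring run
        logger.warning("g2p backend failed on %r / %r; using spelling", a, b)
        return False
    if pa is None or pb is None:
        return False
    return strip_stress(pa) == strip_stress(pb)


def make_matcher(phonetic: G2PBackend | None = None) -> Matcher:
    """Bind a g2p backend into a two-token matcher; ``homophone_matcher()``
    built on the bundled lexicon is the common case."""
    if phonetic is None:
        return lambda a, b: a == b
    return lambda a, b: words_match(a, b, phonetic)


def homophone_matcher() -> Matcher:
    """Matcher using the built-in homophone lexicon."""
    return make_matcher(builtin_lexicon_g2p)


def score_sentences(
    results: Sequence[Sequence[str]],
    transcripts: Sequence[Sequence[str]],
    matcher: Matcher | None = None,
) -> ScoreResult:
    """Order-insensitive sentence scoring, pooled over a sentence set.

    Per sentence, the correct-word count is the size of the multiset
    intersection between result and transcript tokens; the pooled total is
    the number of transcript words. With a homophone-aware matcher, an
    unmatched result word may also pair with a remaining homophonous
    transcript word.
    """
    if len(results) != len(transcripts):
        raise ValueError(
            f"got {len(results)} results for {len(transcripts)} transcripts"
        )
    if not transcripts:
        raise ValueError("need at least one transcript")
    total = ScoreResult(0, 0)
    for res, ref in zip(results, transcripts):
        res_c, ref_c = Counter(res), Counter(ref)
        common = res_c & ref_c
        n = sum(common.values())
        if matcher is not None:
            # pair leftover words across the two multisets by homophony
            res_left = list((res_c - common).elements())
            ref_left = list((ref_c - common).elements())
            for w in res_left:
                for i, t in enumerate(ref_left):
                    if matcher(w, t):
                        del ref_left[i]
                        n += 1
                        break
        total = total + ScoreResult(min(n, sum(ref_c.values())), sum(ref_c.values()))
    return total


def _positional_similarity(a: Sequence[str], b: Sequence[str], match: Matcher) -> int:
    return sum(1 for x, y in zip(a, b) if match(x, y))


def align_and_score_words(
    result: Sequence[str],
    transcript: Sequence[str],
    matcher: Matcher | None = None,
) -> ScoreResult:
    """Greedy word-by-word alignment scoring of a word list.

    While the two lists differ in length, every single word of the longer
    list is trial-deleted in turn; the positional similarity of the
    remaining words is computed for each trial, and the deletion giving the
    highest similarity is made permanent (leftmost on ties). When lengths
    are equal the score is the count of matching positions, out of the
    transcript length.
    """
    if len(transcript) == 0:
        raise ValueError("transcript must be non-empty")
    match = matcher or (lambda a, b: a == b)
    r, t = list(result), list(transcript)
    while len(r) != len(t):
        longer, other = (r, t) if len(r) > len(t) else (t, r)
        best, best_i = -1, 0
        for i in range(len(longer)):
            trial = longer[:i] + longer[i + 1:]
            s = _positional_similarity(trial, other, match)
            if s > best:
                best, best_i = s, i
        del longer[best_i]
    return ScoreResult(_positional_similarity(r, t, match), len(transcript))


def brute_force_alignment_score(
    result: Sequence[str],
    transcript: Sequence[str],
    matcher: Matcher | None = None,
    max_size: int = 16,
) -> ScoreResult:
    """Exact optimum of the word-list alignment score by full enumeration.

    Every deletion set that equalizes the list lengths is tried; the best
    positional-match count is returned. Exponential in the surplus — a test
    oracle for the greedy search, guarded by ``max_size`` on combined length.
    """
    if len(transcript) == 0:
        raise ValueError("transcript must be non-empty")
    if len(result) + len(transcript) > max_size:
        raise ValueError(
            f"instance too large for exhaustive search "
            f"({len(result)}+{len(transcript)} tokens > max_size={max_size})"
        )
    match = matcher or (lambda a, b: a == b)
    r, t = list(result), list(transcript)
    longer, other = (r, t) if len(r) >= len(t) else (t, r)
    surplus = len(longer) - len(other)
    best = 0
    idx = range(len(longer))
    for keep in itertools.combinations(idx, len(longer) - surplus) if surplus else [tuple(idx)]:
        trimmed = [longer[i] for i in keep]
        best = max(best, _positional_similarity(trimmed, other, match))
        if best == len(other):
            break
    return ScoreResult(min(best, len(transcript)), len(transcript))
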