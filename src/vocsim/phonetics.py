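"""Grapheme-to-phoneme backends for homophone-aware word matching.

A backend maps a cleaned token to a phoneme sequence (ARPAbet-style strings,
lexical stress as trailing digits) or ``None`` when the word is unknown.
The built-in backend is a compact hand-curated pronouncing lexicon covering
common English homophone sets — enough for homophone-aware scoring of
typical test materials without any external model. Users with the g2p-en
package installed can plug it in via :class:`vocsim.adapters.G2pEnBackend`.
"""

from __future__ import annotations

from typing import Optional, Sequence

# Hand-written ARPAbet pronunciations (with stress digits) for frequent
# English homophone groups. Synthetic lexicon: compiled by hand for this
# package, not extracted from any pronouncing dictionary distribution.
_LEXICON: dict[str, tuple[str, ...]] = {
    "wine": ("W", "AY1", "N"),
    "whine": ("W", "AY1", "N"),
    "there": ("DH", "EH1", "R"),
    "their": ("DH", "EH1", "R"),
    "theyre": ("DH", "EH1", "R"),
    "to": ("T", "UW1"),
    "too": ("T", "UW1"),
    "two": ("T", "UW1"),
    "sea": ("S", "IY1"),
    "see": ("S", "IY1"),
    "hear": ("HH", "IH1", "R"),
    "here": ("HH", "IH1", "R"),
    "night": ("N", "AY1", "T"),
    "knight": ("N", "AY1", "T"),
    "right": ("R", "AY1", "T"),
    "write": ("R", "AY1", "T"),
    "rite": ("R", "AY1", "T"),
    "sun": ("S", "AH1", "N"),
    "son": ("S", "AH1", "N"),
    "pair": ("P", "EH1", "R"),
    "pear": ("P", "EH1", "R"),
    "pare": ("P", "EH1", "R"),
    "by": ("B", "AY1"),
    "buy": ("B", "AY1"),
    "bye": ("B", "AY1"),
    "ate": ("EY1", "T"),
    "eight": ("EY1", "T"),
    "flour": ("F", "L", "AW1", "ER0"),
    "flower": ("F", "L", "AW1", "ER0"),
    "meat": ("M", "IY1", "T"),
    "meet": ("M", "IY1", "T"),
    "one": ("W", "AH1", "N"),
    "won": ("W", "AH1", "N"),
    "new": ("N", "UW1"),
    "knew": ("N", "UW1"),
    "blue": ("B", "L", "UW1"),
    "blew": ("B", "L", "UW1"),
    "no": ("N", "OW1"),
    "know": ("N", "OW1"),
    "hour": ("AW1", "ER0"),
    "our": ("AW1", "ER0"),
    "weak": ("W", "IY1", "K"),
    "week": ("W", "IY1", "K"),
    "plane": ("P", "L", "EY1", "N"),
    "plain": ("P", "L", "EY1", "N"),
    "sail": ("S", "EY1", "L"),
    "sale": ("S", "EY1", "L"),
    "tale": ("T", "EY1", "L"),
    "tail": ("T", "EY1", "L"),
    "bear": ("B", "EH1", "R"),
    "bare": ("B", "EH1", "R"),
    "steel": ("S", "T", "IY1", "L"),
    "steal": ("S", "T", "IY1", "L"),
    "cell": ("S", "EH1", "L"),
    "sell": ("S", "EH1", "L"),
    "some": ("S", "AH1", "M"),
    "sum": ("S", "AH1", "M"),
    "for": ("F", "AO1", "R"),
    "four": ("F", "AO1", "R"),
    "fore": ("F", "AO1", "R"),
    "hole": ("HH", "OW1", "L"),
    "whole": ("HH", "OW1", "L"),
    "made": ("M", "EY1", "D"),
    "maid": ("M", "EY1", "D"),
    "mail": ("M", "EY1", "L"),
    "male": ("M", "EY1", "L"),
    "peace": ("P", "IY1", "S"),
    "piece": ("P", "IY1", "S"),
    "role": ("R", "OW1", "L"),
    "roll": ("R", "OW1", "L"),
    "scene": ("S", "IY1", "N"),
    "seen": ("S", "IY1", "N"),
    "stair": ("S", "T", "EH1", "R"),
    "stare": ("S", "T", "EH1", "R"),
    "threw": ("TH", "R", "UW1"),
    "through": ("TH", "R", "UW1"),
    "toe": ("T", "OW1"),
    "tow": ("T", "OW1"),
    "wait": ("W", "EY1", "T"),
    "weight": ("W", "EY1", "T"),
    "waist": ("W", "EY1", "S", "T"),
    "waste": ("W", "EY1", "S", "T"),
    "way": ("W", "EY1"),
    "weigh": ("W", "EY1"),
    "wood": ("W", "UH1", "D"),
    "would": ("W", "UH1", "D"),
    "cat": ("K", "AE1", "T"),
    "dog": ("D", "AO1", "G"),
}


def builtin_lexicon_g2p(word: str) -> Optional[tuple[str, ...]]:
    """Look a cleaned token up in the built-in pronouncing lexicon.

    Returns the phoneme sequence (stress digits included) or ``None`` for
    out-of-lexicon words, in which case matching falls back to spelling.
    """
    return _LEXICON.get(word)


def strip_stress(phones: Sequence[str]) -> tuple[str, ...]:
    """Remove lexical-stress digits (``AY1`` → ``AY``) so that homophones
    annotated with different stress still compare equal."""
    return tuple(p.rstrip("0123456789") for p in phones)
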