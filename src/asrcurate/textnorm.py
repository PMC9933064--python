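"""Text normalization onto the restricted character vocabulary of the acoustic model.

The acoustic model emits characters from a small vocabulary: the 26 basic Latin
letters, space, dash and apostrophe. Manual transcripts and ASR hypotheses are
mapped onto this vocabulary before any alignment or error computation, so that
"Hé," and "he" compare equal. Accented letters are reduced to their base letter
(the model has no accented characters), all other symbols become word
separators, and text is lower-cased.

All alignment and WER code in this package operates on :class:`NormalizedText`.
"""

from __future__ import annotations

import logging
import string
import unicodedata
from dataclasses import dataclass, field

__all__ = ["NormalizationConfig", "NormalizedText", "normalize", "to_characters"]

logger = logging.getLogger(__name__)

_ASCII_LETTERS = frozenset(string.ascii_lowercase)
_DIGITS = frozenset(string.digits)

#: Characters translated to ASCII equivalents before filtering. Typographic
#: apostrophes become ASCII apostrophes; em/en dashes and similar pause
#: punctuation become spaces (they separate words, they do not join them).
_PRE_TRANSLATE = str.maketrans(
    {
        "’": "'",  # right single quotation mark
        "‘": "'",  # left single quotation mark
        "ʼ": "'",  # modifier letter apostrophe
        "—": " ",  # em dash
        "–": " ",  # en dash
        "‒": " ",  # figure dash
        "―": " ",  # horizontal bar
    }
)


@dataclass(frozen=True)
class NormalizationConfig:
    """Rules mapping raw text onto the model's character vocabulary.

    Parameters
    ----------
    keep_characters
        Allowed output characters. Always contains the 26 basic Latin
        letters and the space; dash and apostrophe are allowed by default.
    strip_accents
        Reduce accented letters to their unaccented base letter
        (canonical decomposition, combining marks removed).
    case_fold
        Lower-case everything. Case carries no information for WER.
    digit_policy
        ``"drop"`` replaces digits with spaces (logged once per call);
        ``"keep_verbatim"`` keeps them as word characters.
    """

    keep_characters: frozenset[str] = frozenset(string.ascii_lowercase + " -'")
    strip_accents: bool = True
    case_fold: bool = True
    digit_policy: str = "drop"

    def __post_init__(self) -> None:
        missing = (_ASCII_LETTERS | {" "}) - set(self.keep_characters)
        if missing:
            raise ValueError(
                f"keep_characters must contain a-z and space; missing {sorted(missing)!r}"
            )
        if self.digit_policy not in ("drop", "keep_verbatim"):
            raise ValueError(f"unknown digit_policy {self.digit_policy!r}")
        object.__setattr__(self, "keep_characters", frozenset(self.keep_characters))

    @property
    def effective_alphabet(self) -> frozenset[str]:
        if self.digit_policy == "keep_verbatim":
            return self.keep_characters | _DIGITS
        return self.keep_characters


DEFAULT_CONFIG = NormalizationConfig()


@dataclass(frozen=True)
class NormalizedText:
    """An ordered word-token sequence over the allowed character set.

    The unit of all alignment and WER computation. Tokens are non-empty,
    contain no whitespace, and use only allowed characters. Normalization is
    idempotent: normalizing the rendering of a NormalizedText reproduces it.
    """

    tokens: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        for tok in self.tokens:
            if not tok or any(ch.isspace() for ch in tok):
                raise ValueError(f"invalid token {tok!r}")

    @property
    def char_string(self) -> str:
        """Space-joined character rendering of the token sequence."""
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __bool__(self) -> bool:
        return bool(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def _strip_accents(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize(raw_text: str, config: NormalizationConfig = DEFAULT_CONFIG) -> NormalizedText:
    """Map arbitrary Unicode text onto the allowed vocabulary and tokenize.

    Any disallowed character is replaced by a single space before
    tokenization, so punctuation separates words and never glues them
    together. Never raises on content: any input yields a (possibly empty)
    :class:`NormalizedText`.
    """
    text = raw_text.translate(_PRE_TRANSLATE)
    if config.strip_accents:
        text = _strip_accents(text)
    if config.case_fold:
        text = text.lower()
    if config.digit_policy == "drop" and any(ch in _DIGITS for ch in text):
        logger.warning("digits encountered and dropped during normalization")
    alphabet = config.effective_alphabet
    filtered = "".join(ch if (ch in alphabet and ch != " ") else " " for ch in text)
    return NormalizedText(tuple(filtered.split()))


def to_characters(text: NormalizedText) -> list[str]:
    """Character sequence of the tokens joined by single spaces.

    This is the unit sequence for character-level error analysis; it
    round-trips with the token list (split on space).
    """
    return list(text.char_string)
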