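"""Tokenizer for the multistate model language.

Identifiers are runs of letters, digits and underscores that are not pure
numbers; a leading digit is allowed (ribosome-complex names such as
``80S_aatRNA_eEF1A_GTP`` are legal identifiers). Whitespace is
insignificant everywhere, so ``p{0:10}`` and ``p {0:10 }`` tokenize
identically.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List


class LexError(ValueError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{line}:{col}: {message}")
        self.message = message
        self.line = line
        self.col = col


@dataclass(frozen=True)
class Token:
    kind: str  # IDENT NUMBER ARROW ASSIGN SYM EOF
    value: str
    line: int
    col: int


_WORD_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")
_SYMBOLS = set("+-*/^(){},;:=.~")


def tokenize(text: str, line_offset: int = 1) -> List[Token]:
    """Tokenize *text*; positions are 1-based, lines offset by *line_offset*."""
    tokens: List[Token] = []
    line = line_offset
    col = 1
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if ch == "#":  # comment to end of line
            while i < n and text[i] != "\n":
                i += 1
            continue
        start_col = col
        if ch in _WORD_CHARS:
            j = i
            while j < n and text[j] in _WORD_CHARS:
                j += 1
            word = text[i:j]
            if word.isdigit():
                # possible decimal fraction: 7.8 (but not a site accessor,
                # which always follows an identifier)
                if j + 1 < n and text[j] == "." and text[j + 1].isdigit():
                    k = j + 1
                    while k < n and text[k].isdigit():
                        k += 1
                    word = text[i:k]
                    j = k
                tokens.append(Token("NUMBER", word, line, start_col))
            else:
                tokens.append(Token("IDENT", word, line, start_col))
            col += j - i
            i = j
            continue
        if ch == "-" and i + 1 < n and text[i + 1] == ">":
            tokens.append(Token("ARROW", "->", line, start_col))
            i += 2
            col += 2
            continue
        if ch == ":" and i + 1 < n and text[i + 1] == "=":
            tokens.append(Token("ASSIGN", ":=", line, start_col))
            i += 2
            col += 2
            continue
        if ch in _SYMBOLS:
            tokens.append(Token("SYM", ch, line, start_col))
            i += 1
            col += 1
            continue
        raise LexError(f"unexpected character {ch!r}", line, col)
    tokens.append(Token("EOF", "", line, col))
    return tokens
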