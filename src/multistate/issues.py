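"""Severity-graded diagnostics.

A model carrying issues of any severity remains constructible and
serializable; callers decide when (and whether) to act on them.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"


@dataclass(frozen=True)
class ValidationIssue:
    """One diagnostic: severity, short machine code, location, message.

    ``location`` is a (line, column) pair when the issue maps back to
    source text, else None (issues raised on programmatically built
    models have no text location).
    """

    severity: Severity
    code: str
    message: str
    location: Optional[Tuple[int, int]] = field(default=None)

    def to_json(self) -> str:
        line, col = self.location if self.location else (None, None)
        return json.dumps(
            {
                "severity": self.severity.value,
                "code": self.code,
                "line": line,
                "column": col,
                "message": self.message,
            }
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f"{self.location[0]}:{self.location[1]}: " if self.location else ""
        return f"{loc}{self.severity.value}[{self.code}]: {self.message}"


def errors(issues) -> list:
    """The subset of *issues* with error severity."""
    return [i for i in issues if i.severity is Severity.ERROR]


def issues_to_jsonl(issues) -> str:
    """Serialize diagnostics as JSON lines (one object per line)."""
    return "\n".join(i.to_json() for i in issues)
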