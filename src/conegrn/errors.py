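"""Error type carrying a short machine-readable code.

Every contract violation in the pipeline raises :class:`PipelineError` with a
stable ``code`` (e.g. ``"empty-group"``, ``"mtx-shape"``) so callers can match
on the failure mode without parsing messages.
"""

from __future__ import annotations


class PipelineError(ValueError):
    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message if message is not None else code)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        base = super().__str__()
        return f"[{self.code}] {base}" if base != self.code else self.code
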