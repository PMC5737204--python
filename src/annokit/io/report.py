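"""Import bookkeeping shared by all readers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ImportReport:
    """What an import materialized and what it had to skip.

    ``skipped`` holds (locator, reason) pairs — a line number or XML
    element id plus a human-readable reason.  Unsupported constructs are
    skipped loudly, never silently.
    """

    n_documents: int = 0
    n_entities: int = 0
    n_relations: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def skip(self, locator: str, reason: str) -> None:
        self.skipped.append((locator, reason))
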