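"""Audit configuration: thresholds, toggles and vocabulary, in one object.

Every :class:`~paleoaudit.criteria.StudyVerdict` records a content digest of
the configuration it was produced under, so that verdicts evaluated under
different thresholds are never aggregated together.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .crosscheck import DEFAULT_SUFFIX_TOKENS
from .metadata_audit import Lexicons

__all__ = ["AuditConfig"]


@dataclass
class AuditConfig:
    """Tunable parameters of a study audit.

    ``mapq_trigger`` / ``length_trigger`` are the floors at or above which an
    observed per-file minimum is read as evidence of hard filtering (25 and
    30: the thresholds at which archived ancient-DNA alignment files are
    commonly filtered).  ``min_confident_n`` guards both inferences against
    small files.  ``adapter_threshold`` is the residue fraction above which a
    raw file counts as untrimmed; 1% tolerates chance matches in
    adapter-free data.
    """

    n_sample: int = 10_000
    mapq_trigger: int = 25
    length_trigger: int = 30
    min_confident_n: int = 1000
    adapter_threshold: float = 0.01
    adapter_min_overlap: int = 8
    adapter_max_mismatch_rate: float = 0.1
    case_insensitive_match: bool = False
    suffix_tokens: tuple[str, ...] = DEFAULT_SUFFIX_TOKENS
    lexicons: Optional[Lexicons] = None

    def __post_init__(self):
        if self.lexicons is None:
            self.lexicons = Lexicons.default()
        self.suffix_tokens = tuple(self.suffix_tokens)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["suffix_tokens"] = list(self.suffix_tokens)
        return d

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AuditConfig":
        """Load from a YAML/JSON document; unknown keys are rejected."""
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        lex = doc.pop("lexicons", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if lex is not None:
            base = Lexicons.default()
            for name, values in lex.items():
                setattr(base, name, list(values))
            cfg.lexicons = base
        return cfg
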