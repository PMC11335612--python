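"""Small shared helpers: decimal rounding, hashing, JSON encoding."""

from __future__ import annotations

import hashlib
import json
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reported percentages use this,
    not banker's rounding)."""
    if math.isinf(x) or math.isnan(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


class _JsonEncoder(json.JSONEncoder):
    """Serializes infinities as the string "inf" and sets as sorted lists."""

    def default(self, o: Any) -> Any:  # noqa: D102
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)

    def iterencode(self, o: Any, _one_shot: bool = False):
        return super().iterencode(_sanitize(o), _one_shot)


def _sanitize(obj: Any) -> Any:
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if math.isnan(obj):
            return "nan"
        return obj
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_sanitize(v) for v in obj)
    return obj


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(to_json(obj), encoding="utf-8")


def to_json(obj: Any) -> str:
    return json.dumps(_sanitize(obj), indent=2, sort_keys=True, cls=_JsonEncoder) + "\n"
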