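"""Flat typed key-value config files (``key = value`` per line, ``#`` comments)."""

from __future__ import annotations

from pathlib import Path

__all__ = ["parse_kv", "format_kv"]


def _coerce(text: str):
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null", ""):
        return None
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            pass
    return text


def parse_kv(source: str | Path) -> dict:
    """Parse a flat config from a path or literal text."""
    path = Path(source) if not isinstance(source, str) or "\n" not in source else None
    if path is not None and path.exists():
        text = path.read_text()
    else:
        text = str(source)
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = _coerce(value)
    return out


def format_kv(config: dict) -> str:
    return "".join(f"{k} = {v}\n" for k, v in config.items())
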