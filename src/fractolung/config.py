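"""Flat key-value config files (one ``key = value`` per line, ``#`` comments).

Values are coerced to int, float, or bool when they parse as one; everything
else stays a string.  Used by the CLI's ``--config`` option.
"""

from __future__ import annotations

from pathlib import Path

from fractolung.errors import ConfigurationError


def _coerce(raw: str):
    s = raw.strip()
    low = s.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        pass
    return s


def read_config(path) -> dict:
    """Parse a flat key-value config file into a typed dict."""
    text = Path(path).read_text()
    out: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'key = value', got {line!r}"
            )
        key, _, value = stripped.partition("=")
        key = key.strip()
        if not key:
            raise ConfigurationError(f"{path}:{lineno}: empty key")
        out[key] = _coerce(value)
    return out


def write_config(values: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")
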