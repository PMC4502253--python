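"""Flat key-value configuration files.

Format: one ``key = value`` pair per line; blank lines and ``#`` comments
ignored.  No nesting, no quoting — values are parsed by the consumer.
"""

from __future__ import annotations

from pathlib import Path


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = stripped.split("=", 1)
        key = key.strip()
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = value.strip()
    return out


def write_config(values: dict, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")
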