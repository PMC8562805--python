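"""Tiny persistent JSON key-value store for filter decisions and ddG values.

One JSON object per file; keys are caller-built strings.  Writes are
atomic-ish (write to temp, rename) so an interrupted run cannot corrupt
earlier entries.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Any


class JsonFileCache:
    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._data: dict[str, Any] = {}
        if self.path.exists():
            with open(self.path) as fh:
                self._data = json.load(fh)
        self.hits = 0
        self.misses = 0

    def __contains__(self, key: str) -> bool:
        return key in self._data

    def get(self, key: str) -> Any | None:
        if key in self._data:
            self.hits += 1
            return self._data[key]
        self.misses += 1
        return None

    def put(self, key: str, value: Any) -> None:
        self._data[key] = value
        self._flush()

    def _flush(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        tmp = self.path.with_suffix(self.path.suffix + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(self._data, fh, indent=0, sort_keys=True)
        os.replace(tmp, self.path)

    def __len__(self) -> int:
        return len(self._data)


class NullCache(JsonFileCache):
    """In-memory stand-in when no cache directory is configured."""

    def __init__(self):  # noqa: D107
        self._data = {}
        self.hits = 0
        self.misses = 0

    def _flush(self) -> None:
        pass
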