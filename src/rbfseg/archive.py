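"""A minimal study archive: an append-only JSON manifest over image files.

This is the storage flavor of a picture archive: each study id maps to its
image (and optionally label image and model) paths plus a class-count
summary, a creation timestamp, and SHA-256 content hashes.  Hashes are
verified when entries are read back, so silent file tampering or corruption
surfaces as an :class:`ArchiveError`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .exceptions import ArchiveError, InputError

__all__ = ["Archive", "archive_add", "archive_query"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Archive:
    """Manifest-backed file archive keyed by study id."""

    manifest_path: Path
    entries: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def open(cls, manifest_path: str | Path) -> "Archive":
        manifest_path = Path(manifest_path)
        entries: dict[str, dict] = {}
        if manifest_path.exists():
            entries = json.loads(manifest_path.read_text())["entries"]
        return cls(manifest_path=manifest_path, entries=entries)

    def save(self) -> None:
        self.manifest_path.parent.mkdir(parents=True, exist_ok=True)
        self.manifest_path.write_text(
            json.dumps({"entries": self.entries}, indent=1, sort_keys=True)
        )

    def add(
        self,
        study_id: str,
        image_path: str | Path,
        label_path: str | Path | None = None,
        model_path: str | Path | None = None,
        class_counts: dict[int, int] | None = None,
    ) -> dict:
        """Register a study; duplicate ids and missing files are errors."""
        if study_id in self.entries:
            raise ArchiveError(f"study id {study_id!r} already archived")
        paths = {"image": Path(image_path)}
        if label_path is not None:
            paths["labels"] = Path(label_path)
        if model_path is not None:
            paths["model"] = Path(model_path)
        for role, p in paths.items():
            if not p.exists():
                raise InputError(f"{role} file does not exist: {p}")
        entry = {
            "paths": {role: str(p) for role, p in paths.items()},
            "hashes": {role: _sha256(p) for role, p in paths.items()},
            "class_counts": (
                None
                if class_counts is None
                else {str(k): int(v) for k, v in class_counts.items()}
            ),
            "created": datetime.now(timezone.utc).isoformat(),
        }
        self.entries[study_id] = entry
        self.save()
        return entry

    def get(self, study_id: str, verify: bool = True) -> dict:
        if study_id not in self.entries:
            raise ArchiveError(f"no study {study_id!r} in archive")
        entry = self.entries[study_id]
        if verify:
            self.verify(study_id)
        return entry

    def verify(self, study_id: str) -> None:
        """Re-hash the entry's files; mismatch or absence raises."""
        entry = self.entries[study_id]
        for role, p in entry["paths"].items():
            p = Path(p)
            if not p.exists():
                raise ArchiveError(f"{study_id}: {role} file missing: {p}")
            if _sha256(p) != entry["hashes"][role]:
                raise ArchiveError(
                    f"{study_id}: {role} file content hash mismatch "
                    f"(file changed since archiving): {p}"
                )

    def query(self, study_id: str | None = None, predicate=None) -> dict[str, dict]:
        """Entries matching an id and/or a predicate on the entry dict.

        An empty filter returns every entry.
        """
        items = self.entries.items()
        if study_id is not None:
            items = [(k, v) for k, v in items if k == study_id]
        if predicate is not None:
            items = [(k, v) for k, v in items if predicate(v)]
        return dict(items)


def archive_add(manifest_path, study_id, image_path, **kwargs) -> Archive:
    """Functional wrapper: open, add, persist; returns the archive."""
    archive = Archive.open(manifest_path)
    archive.add(study_id, image_path, **kwargs)
    return archive


def archive_query(manifest_path, study_id=None, predicate=None) -> dict[str, dict]:
    return Archive.open(manifest_path).query(study_id, predicate)
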