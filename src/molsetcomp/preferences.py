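"""Persistent preferences, stored as an XML document.

Defaults apply when no file exists; command-line flags always override file
values.  Unknown keys in a preference file are ignored with a logged
warning, and a malformed file falls back to the defaults rather than
aborting a run.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, fields
from pathlib import Path

log = logging.getLogger(__name__)

DEFAULT_PREFS_FILENAME = "molsetcomp_preferences.xml"


@dataclass
class Preferences:
    image_dir: str = "."
    molecule_list_dir: str = "."
    summary_dir: str = "."
    results_dir: str = "."
    input_dir: str = "."
    n_threads: int = 1
    max_pairs_reported: int = 1000
    default_n_bins: int = 10
    image_dpi: int = 150

    def __post_init__(self) -> None:
        for name in ("n_threads", "max_pairs_reported", "default_n_bins", "image_dpi"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


_INT_FIELDS = {"n_threads", "max_pairs_reported", "default_n_bins", "image_dpi"}


def save_preferences(prefs: Preferences, path: str | Path) -> None:
    root = ET.Element("preferences")
    for f in fields(prefs):
        el = ET.SubElement(root, f.name)
        el.text = str(getattr(prefs, f.name))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(Path(path), encoding="utf-8", xml_declaration=True)


def load_preferences(path: str | Path | None) -> Preferences:
    """Load preferences; absent or malformed files yield the defaults."""
    if path is None or not Path(path).exists():
        return Preferences()
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as exc:
        log.warning("malformed preferences file %s (%s); using defaults", path, exc)
        return Preferences()
    known = {f.name for f in fields(Preferences)}
    kwargs = {}
    for el in root:
        if el.tag not in known:
            log.warning("ignoring unknown preference key %r in %s", el.tag, path)
            continue
        text = (el.text or "").strip()
        kwargs[el.tag] = int(text) if el.tag in _INT_FIELDS else text
    return Preferences(**kwargs)
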