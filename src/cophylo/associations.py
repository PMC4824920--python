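"""Host-symbiont association links (the tanglegram's connecting lines)."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .trees import PhyloTree

__all__ = ["AssociationMap"]


@dataclass
class AssociationMap:
    """An ordered list of (host leaf label, symbiont leaf label) links.

    Many-to-many associations are allowed: a host species may carry several
    symbiont lineages and a symbiont may occur on several hosts.
    """

    links: list

    def __post_init__(self):
        self.links = [(str(h), str(s)) for h, s in self.links]
        if not self.links:
            raise ValidationError("association map must contain at least one link")

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    @property
    def host_labels(self) -> list:
        return [h for h, _ in self.links]

    @property
    def symbiont_labels(self) -> list:
        return [s for _, s in self.links]

    def validate_against(self, host: PhyloTree, symbiont: PhyloTree) -> None:
        host_set = set(host.leaf_labels)
        symb_set = set(symbiont.leaf_labels)
        for h, s in self.links:
            if h not in host_set:
                raise ValidationError(f"link host label {h!r} is not a leaf of the host tree")
            if s not in symb_set:
                raise ValidationError(
                    f"link symbiont label {s!r} is not a leaf of the symbiont tree"
                )

    def symbiont_to_host(self) -> dict:
        """Mapping symbiont leaf -> its single host leaf.

        Raises when any symbiont leaf is linked to more than one host, which
        event-based reconciliation does not allow (expand specimen-level
        duplicates into distinct symbiont leaves first).
        """
        out: dict = {}
        for h, s in self.links:
            if s in out and out[s] != h:
                raise ValidationError(
                    f"symbiont leaf {s!r} is linked to multiple hosts ({out[s]!r}, {h!r})"
                )
            out[s] = h
        return out

    def as_matrix(
        self, host_order: Sequence[str], symbiont_order: Sequence[str]
    ) -> np.ndarray:
        """Binary host x symbiont incidence matrix in the given label orders."""
        hi = {l: i for i, l in enumerate(host_order)}
        si = {l: i for i, l in enumerate(symbiont_order)}
        mat = np.zeros((len(host_order), len(symbiont_order)), dtype=int)
        for h, s in self.links:
            mat[hi[h], si[s]] = 1
        return mat

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, host_order: Sequence[str], symbiont_order: Sequence[str]
    ) -> "AssociationMap":
        links = [
            (host_order[i], symbiont_order[j])
            for i, j in zip(*np.nonzero(np.asarray(matrix)))
        ]
        return cls(links)

    @classmethod
    def from_tsv(cls, path) -> "AssociationMap":
        """Read a two-column TSV (host_tip, symbiont_tip); '#' starts a comment."""
        links = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected two columns (host_tip, symbiont_tip)"
                )
            links.append((parts[0], parts[1]))
        return cls(links)

    def to_tsv(self, path) -> None:
        Path(path).write_text("".join(f"{h}\t{s}\n" for h, s in self.links))
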