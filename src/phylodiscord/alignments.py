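"""Amino-acid alignment container and FASTA I/O (Biopython-backed)."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset("-?.")
AMBIGUOUS_CHARS = frozenset("X*")

__all__ = ["Alignment", "GAP_CHARS", "AMBIGUOUS_CHARS"]


@dataclass
class Alignment:
    """Rows of equal length keyed by unique taxon labels."""

    labels: list[str]
    rows: list[str]
    name: str = "aln"
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        self._index = {l: i for i, l in enumerate(self.labels)}

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def sequence(self, label: str) -> str:
        return self.rows[self._index[label]]

    def subset(self, labels) -> "Alignment":
        labels = [l for l in self.labels if l in set(labels)]
        return Alignment(labels, [self.sequence(l) for l in labels], name=self.name)

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]

    @classmethod
    def from_fasta(cls, source, name: str = "aln") -> "Alignment":
        if isinstance(source, str) and "\n" in source:
            handle = io.StringIO(source)
        else:
            handle = open(source)
        try:
            records = list(SeqIO.parse(handle, "fasta"))
        finally:
            handle.close()
        return cls([r.id for r in records], [str(r.seq) for r in records], name=name)

    def to_fasta(self, path=None) -> str:
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(self.labels, self.rows)
        ]
        buf = io.StringIO()
        SeqIO.write(records, buf, "fasta")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
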