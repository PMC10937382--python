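"""Amplicon panel: the targeted amplicons decoded from each read.

The panel mirrors the custom single-cell DNA panel used to read out the
lentiviral cargo: one amplicon spanning the barcode distal to the 5' LTR, one
spanning the matching barcode proximal to the 3' LTR, and a GFP amplicon used
as a transduction marker (it carries no barcode).  Reads are modelled as
upstream flank + 10-nt barcode + downstream flank; the flanks are the
constant vector sequence either side of the barcode insertion site.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import BARCODE_LENGTH

END_5PRIME = "5prime"
END_3PRIME = "3prime"
END_GFP = "gfp"


@dataclass(frozen=True)
class Amplicon:
    """One panel amplicon.  ``window`` is the 0-based half-open interval in
    which the barcode is expected to start/end within a read; the GFP
    amplicon has an empty window (no barcode)."""

    name: str
    upstream: str
    downstream: str
    window: tuple[int, int]
    end_label: str

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("flank sequences must be non-empty")
        if self.end_label not in (END_5PRIME, END_3PRIME, END_GFP):
            raise ValueError(f"unknown end label {self.end_label!r}")
        lo, hi = self.window
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid barcode window {self.window}")
        if self.end_label == END_GFP and hi != lo:
            raise ValueError("GFP amplicon carries no barcode: window must be empty")
        if self.end_label != END_GFP and hi - lo != BARCODE_LENGTH:
            raise ValueError(f"barcode window must span {BARCODE_LENGTH} nt")

    @property
    def has_barcode(self) -> bool:
        return self.end_label != END_GFP

    def template(self, barcode: str = "") -> str:
        """Error-free read sequence for this amplicon."""
        return self.upstream + barcode + self.downstream


class AmpliconPanel:
    """Ordered collection of amplicons with unique names."""

    def __init__(self, amplicons: list[Amplicon]):
        names = [a.name for a in amplicons]
        if len(set(names)) != len(names):
            raise ValueError("amplicon names must be unique")
        self.amplicons = list(amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def by_end(self, end_label: str) -> Amplicon:
        for a in self.amplicons:
            if a.end_label == end_label:
                return a
        raise KeyError(end_label)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "name": a.name,
                "upstream": a.upstream,
                "downstream": a.downstream,
                "window_start": a.window[0],
                "window_end": a.window[1],
                "end_label": a.end_label,
            }
            for a in self.amplicons
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AmpliconPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        amps = [
            Amplicon(
                name=r["name"],
                upstream=r["upstream"],
                downstream=r["downstream"],
                window=(int(r["window_start"]), int(r["window_end"])),
                end_label=r["end_label"],
            )
            for r in df.to_dict("records")
        ]
        return cls(amps)


def default_panel() -> AmpliconPanel:
    """The simulator's amplicon design: 20-nt constant flanks per end.

    Flank sequences are arbitrary fixed vector sequence; what matters is that
    the three amplicons are mutually distinguishable and that each barcode
    sits at offset 20 of its read.
    """
    return AmpliconPanel(
        [
            Amplicon(
                name="LTR5_BC",
                upstream="ACGGTTCACGTAGTGGGCCA",
                downstream="TCGATTAGTGAACGGATCTC",
                window=(20, 30),
                end_label=END_5PRIME,
            ),
            Amplicon(
                name="LTR3_BC",
                upstream="GATCCTTGTACAAAGTGGTC",
                downstream="AATCAACCTCTGGATTACAA",
                window=(20, 30),
                end_label=END_3PRIME,
            ),
            Amplicon(
                name="GFP",
                upstream="ACCACATGAAGCAGCACGAC",
                downstream="TTCAAGTCCGCCATGCCCGA",
                window=(20, 20),
                end_label=END_GFP,
            ),
        ]
    )
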