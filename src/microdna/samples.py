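"""Sample metadata: drug, sensitivity and treatment assignments per sample."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

DRUGS = ("MTX", "ASP")
SENSITIVITIES = ("S", "R")
TREATMENTS = ("T", "NT")
#: The four per-drug condition groups: sensitivity x treatment.
CONDITIONS = ("R_T", "R_NT", "S_T", "S_NT")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    drug: str
    sensitivity: str
    treatment: str

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r} (expected one of {DRUGS})")
        if self.sensitivity not in SENSITIVITIES:
            raise ValueError(f"unknown sensitivity {self.sensitivity!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def condition(self) -> str:
        """Group label within a drug, e.g. 'S_T' for sensitive-treated."""
        return f"{self.sensitivity}_{self.treatment}"

    @property
    def group(self) -> tuple[str, str]:
        return (self.drug, self.condition)


def default_sample_sheet(n_replicates: int = 5) -> list[SampleMeta]:
    """Full factorial design: every drug x sensitivity x treatment cell,
    n_replicates samples each (the default of 5 gives 40 samples)."""
    samples = []
    for drug in DRUGS:
        for sens in SENSITIVITIES:
            for treat in TREATMENTS:
                for i in range(1, n_replicates + 1):
                    samples.append(
                        SampleMeta(f"{drug}_{sens}_{treat}_{i}", drug, sens, treat)
                    )
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdrug\tsensitivity\ttreatment\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.drug}\t{s.sensitivity}\t{s.treatment}\n")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    samples = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["sample_id", "drug", "sensitivity", "treatment"]:
            raise ValueError(f"unexpected sample sheet header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            sid, drug, sens, treat = line.rstrip("\n").split("\t")[:4]
            samples.append(SampleMeta(sid, drug, sens, treat))
    return samples
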