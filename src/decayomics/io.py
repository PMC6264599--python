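"""Tab-separated table I/O and the probe-level container.

All tabular artifacts are TSV with a header row, decimal points (never
commas) and floats serialized at full round-trip precision, so a
write/read cycle preserves values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ValidationError


@dataclass
class ProbeMatrix:
    """Probe-level intensities with the probe -> transcript mapping.

    ``transcripts`` maps probe_id (index) to transcript_id; ``values`` is
    the probes x arrays intensity matrix on the same probe index.
    """

    transcripts: pd.Series
    values: pd.DataFrame

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)

    def validate(self, probes_per_transcript: int | None = None) -> "ProbeMatrix":
        if not self.transcripts.index.equals(self.values.index):
            raise ValidationError("probe annotation and values have different probe ids")
        v = self.values.to_numpy()
        if not np.all(np.isfinite(v)):
            raise ValidationError("probe intensities must be finite")
        if probes_per_transcript is not None:
            per = self.transcripts.groupby(self.transcripts).size()
            if not (per == probes_per_transcript).all():
                bad = per[per != probes_per_transcript].index[:3].tolist()
                raise ValidationError(
                    f"transcripts with wrong probe count (expected "
                    f"{probes_per_transcript}): {bad}"
                )
        return self

    def subset_arrays(self, arrays) -> "ProbeMatrix":
        return ProbeMatrix(self.transcripts, self.values[list(arrays)])

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "transcript_id", self.transcripts)
        return out


def write_probe_matrix(probes: ProbeMatrix, path) -> None:
    write_table(probes.to_frame(), path, index=True)


def read_probe_matrix(path) -> ProbeMatrix:
    df = read_table(path, index_col=0)
    if "transcript_id" not in df.columns:
        raise ValidationError(f"{path}: missing transcript_id column")
    transcripts = df["transcript_id"].astype(str)
    values = df.drop(columns="transcript_id").astype(float)
    return ProbeMatrix(transcripts, values)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a TSV with full-precision floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=None, lineterminator="\n")


def read_table(path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`.

    Malformed rows are reported with their line number.
    """
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed TSV ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc


def write_truth(truth, outdir) -> None:
    outdir = Path(outdir)
    write_table(truth.transcripts, outdir / "truth_transcripts.tsv")
    write_table(truth.affinities, outdir / "truth_affinities.tsv")
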