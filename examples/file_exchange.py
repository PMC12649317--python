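"""The text-file exchange between optimizer and instrument side.

The optimizer writes candidate parameters as `name=value` lines with a
request sequence number; the instrument side answers with per-peak
mass/intensity/FWHM/mass-error lines echoing the sequence number.  Either
side polls until the peer's sequence number advances.
"""

import tempfile
from pathlib import Path

import numpy as np

from quadtune import CandidateEvaluator, EvaluationSpec, VirtualInstrument
from quadtune.fileproto import (
    read_intensities, read_params, write_intensities, write_params,
)

workdir = Path(tempfile.mkdtemp())
param_file = str(workdir / "params.txt")
result_file = str(workdir / "result.txt")

# optimizer side: publish a candidate
candidate = {"CUR": 20.229, "GS1": 15.573, "DP": 163.03, "EP": 11.413}
write_params(param_file, candidate, seq=1)
print("optimizer wrote:", candidate)

# instrument side: read, calibrate + measure, answer
params, seq = read_params(param_file)
instrument = VirtualInstrument(seed=1)
evaluator = CandidateEvaluator(instrument, EvaluationSpec(), np.random.default_rng(1))
fitness, peaks = evaluator(params)
write_intensities(
    result_file,
    [{"mass": p.nominal_mass, "intensity": p.intensity, "fwhm": p.fwhm,
      "mass_error": p.mass_error} for p in peaks],
    seq=seq,
)

# optimizer side: collect the answer
rows, seq_back = read_intensities(result_file)
print(f"instrument answered (seq {seq_back}):")
for row in rows:
    print(f"  m/z {row['mass']:7.2f}  I = {row['intensity']:.3e} cps  "
          f"FWHM = {row['fwhm']:.3f} u  mass err = {row['mass_error']:+.3f} u")
print(f"fitness of this candidate: {fitness:.4f}")
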