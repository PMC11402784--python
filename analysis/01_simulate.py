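#!/usr/bin/env python
"""Generate the synthetic study: a ground-truthed transcriptome of 3'UTRs
in three regulation classes, condition-dependent cross-link tracks whose
signal relocates to 3'UTR termini in the primed state, exponential-decay
conversion time courses, and expression / differential-expression tables.

Writes FASTA, BED, TSV and the truth table under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from utrdecay import io as udio
from utrdecay.benchmarks import SLAM_TIMEPOINTS
from utrdecay.simulate import (CONDITIONS, SimConfig, attach_expression,
                               generate_transcriptome, simulate_crosslinks,
                               simulate_expression_and_de, simulate_slamseq)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    records, truth = generate_transcriptome(cfg)
    udio.write_fasta(records, OUT / "utrs.fasta", seed=seed)
    udio.write_yaml(cfg.to_dict(), OUT / "sim_config.yaml")
    truth.write(OUT / "truth.tsv", seed=seed)

    for cond in CONDITIONS:
        track = simulate_crosslinks(records, truth, cond, cfg)
        udio.write_crosslink_bed(track, OUT / f"crosslinks_{cond}.bed", seed=seed)
        print(f"{cond}: {track.library_size} cDNAs over {len(records)} 3'UTRs")

    slam = simulate_slamseq(truth, SLAM_TIMEPOINTS, cfg)
    udio.write_table(slam, OUT / "slamseq.tsv", seed=seed)
    tpm, de = simulate_expression_and_de(truth, cfg)
    attach_expression(records, tpm)
    udio.write_table(tpm, OUT / "tpm.tsv", seed=seed)
    udio.write_table(de, OUT / "de.tsv", seed=seed)
    udio.write_table(udio.records_to_annotation(records),
                     OUT / "annotation.tsv", seed=seed)
    n_down = sum(1 for r in records if r.regulation_class == "down")
    print(f"wrote {len(records)} 3'UTRs ({n_down} down-class) to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
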