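import numpy as np
import pytest

from utrdecay.core import CrosslinkTrack, UtrRecord
from utrdecay.simulate import SimConfig, generate_transcriptome, simulate_crosslinks


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=90, seed=11)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Records + truth + both condition tracks for a 90-gene simulation."""
    records, truth = generate_transcriptome(small_cfg)
    tracks = {c: simulate_crosslinks(records, truth, c, small_cfg)
              for c in ("naive", "primed")}
    return {"cfg": small_cfg, "records": records, "truth": truth,
            "tracks": tracks}


@pytest.fixture()
def three_gene_fixture():
    """Tiny hand-made records, expression and track for oracle tests."""
    rng = np.random.default_rng(7)
    seqs = {
        "gA": "".join(rng.choice(list("ACGT"), 400)),
        "gB": "".join(rng.choice(list("ACGT"), 350)),
        "gC": "".join(rng.choice(list("ACGT"), 500)),
    }
    records = []
    for g, s in seqs.items():
        s = s.replace("AATAAA", "AATCAA")
        pas = len(s) - 30 - 6
        s = s[:pas] + "AATAAA" + s[pas + 6:]
        records.append(UtrRecord(gene_id=g, sequence=s, pas_position=pas))
    track = CrosslinkTrack("toy")
    for rec in records:
        vec = np.zeros(rec.width, dtype=int)
        hits = rng.integers(0, rec.width, size=60)
        np.add.at(vec, hits, rng.integers(1, 30, size=60))
        track.set_gene(rec.gene_id, vec)
    expr = {"gA": 4.0, "gB": 10.0, "gC": 2.5}
    return records, track, expr
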