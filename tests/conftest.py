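import numpy as np
import pytest

from promscan.io_formats import CtssTrack, GenomicInterval, SignalTrack
from promscan.promoter_classification import TssRecord
from promscan.synthetic_data import SimConfig, simulate_study
from promscan.tss_clustering import TssCluster


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A full synthetic study (50 promoters per class), shared by tests."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = SimConfig(seed=1)
    objects, truth = simulate_study(cfg, outdir)
    return {"config": cfg, "outdir": outdir, "objects": objects, "truth": truth}


def make_record(chrom, anchor, strand="+", label="X", total=10):
    """A minimal TssRecord anchored at one base, for window-based tests."""
    cluster = TssCluster(
        interval=GenomicInterval(chrom, anchor, anchor + 1, strand),
        total_count=total,
        anchor=anchor,
        min_density=0.0,
        max_density=float(total),
        n_sites=1,
    )
    return TssRecord(cluster=cluster, class_label=label)


@pytest.fixture
def constant_signal():
    return SignalTrack({"chr1": np.full(10_000, 3.0)})


@pytest.fixture
def single_site_track():
    return CtssTrack.from_records([("chr1", 100, "+", 5)])
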