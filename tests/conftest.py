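import numpy as np
import pytest

from tilscape.io_formats import ClonotypeRecord
from tilscape.repertoire import ClonotypeTable


def make_table(sample_id, counts, prefix="CLN"):
    """Clonotype table with distinct CDR3s and the given counts."""
    records = [
        ClonotypeRecord(cdr3_nt=f"{prefix}{i:04d}", cdr3_aa=f"A{i}",
                        v_segment="TRBV1", j_segment="TRBJ1", count=c)
        for i, c in enumerate(counts)
    ]
    return ClonotypeTable.from_records(sample_id, records)


def table_from_clones(sample_id, clone_counts):
    """Table from a {clone_name: count} mapping (clone name = CDR3 nt)."""
    records = [
        ClonotypeRecord(cdr3_nt=name, cdr3_aa="A", v_segment="TRBV1",
                        j_segment="TRBJ1", count=c)
        for name, c in clone_counts.items()
    ]
    return ClonotypeTable.from_records(sample_id, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
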