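import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from asrna_screen.records import GeneRecord, GenomicInterval, SmallRNARecord, Strand


def make_gene(start, end, strand=Strand.PLUS, gene_id="G1", chrom="chrT"):
    return GeneRecord(gene_id, GenomicInterval(chrom, start, end, strand))


def make_srna(start, end, strand=Strand.MINUS, srna_id="s1", chrom="chrT"):
    return SmallRNARecord(srna_id, GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def gene_plus():
    return make_gene(1001, 2000, Strand.PLUS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_dna(rng, n, gc=0.5):
    return "".join(
        rng.choice(np.array(list("GCAT")), size=n, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    )


def random_geometry(rng, chrom_len=300):
    """A random gene/sRNA pair on a toy chromosome, all strand combinations."""
    gs, ge = sorted(rng.integers(1, chrom_len + 1, size=2))
    ss, se = sorted(rng.integers(1, chrom_len + 1, size=2))
    g_strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
    s_strand = [Strand.PLUS, Strand.MINUS, Strand.UNKNOWN][int(rng.integers(0, 3))]
    gene = make_gene(int(gs), int(ge), g_strand)
    srna = make_srna(int(ss), int(se), s_strand)
    return gene, srna
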