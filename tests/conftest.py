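import pandas as pd
import pytest

from panelkit.panel import Amplicon, PanelDesign, locus_map, replica_panel


@pytest.fixture(scope="session")
def panel273():
    return replica_panel()


@pytest.fixture(scope="session")
def loci273(panel273):
    return locus_map(panel273)


@pytest.fixture(scope="session")
def refs273(loci273):
    return {a: l.ref for a, l in loci273.items()}


@pytest.fixture(scope="session")
def small_panel():
    """Six amplicons over three genes; AR has a two-amplicon block."""
    amps = []
    layout = [("AR", "chrX"), ("TP53", "chr17"), ("SPOP", "chr2")]
    for gi, (gene, chrom) in enumerate(layout):
        for j in range(2):
            start = 10_000 * (gi + 1) + j * 500
            amps.append(
                Amplicon(id=f"{gene}_{j + 1:03d}", gene=gene, chrom=chrom,
                         start=start, end=start + 100)
            )
    return PanelDesign(tuple(amps))


@pytest.fixture(scope="session")
def small_loci(small_panel):
    return locus_map(small_panel)


@pytest.fixture(scope="session")
def small_refs(small_loci):
    return {a: l.ref for a, l in small_loci.items()}


def reads_frame(rows):
    """Build a tagged-read table from (amplicon_id, umi, strand, allele) tuples."""
    df = pd.DataFrame(rows, columns=["amplicon_id", "umi", "strand", "allele"])
    df["amplicon_id"] = df["amplicon_id"].astype("category")
    df["strand"] = pd.Categorical(df["strand"], categories=["F", "R"])
    df["allele"] = pd.Categorical(df["allele"], categories=list("ACGT"))
    return df


def families_frame(rows):
    """Build a family table from
    (amplicon_id, umi, strand, size, consensus_allele, consensus_reads) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["amplicon_id", "umi", "strand", "size", "consensus_allele", "consensus_reads"],
    )
    df["agreement"] = df["consensus_reads"] / df["size"]
    return df
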