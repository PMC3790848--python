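# Crystal structures for the reproduction tests

Four acceptance tests reproduce published per-structure numbers on p53-family
DNA-binding-domain crystal structures.  The coordinate files are not
redistributed with this package; to run those tests, download the entries
from the Protein Data Bank and save them here as lower-case `<id>.pdb`:

    data/pdb/2ocj.pdb   # Homo sapiens p53 DBD
    data/pdb/1hu8.pdb   # Mus musculus p53 DBD
    data/pdb/1t4w.pdb   # C. elegans p53 DBD

e.g.

    curl -o data/pdb/2ocj.pdb https://files.rcsb.org/download/2OCJ.pdb

Everything else in the test suite and `scripts/acceptance.py` runs offline on
synthetic fixtures.
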