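# Reference assembly (not bundled)

The deposited-assembly statistics test reads `CBYO01.fasta` from this
directory: the ~4 Mb draft genome of *Paucisalibacillus algeriensis*
strain EB02^T (EMBL/ENA accession CBYO000000000, 23 contigs). The file is
too large to ship with the source tree, so fetch it once, e.g.:

    curl -o data/reference/CBYO01.fasta \
      "https://www.ebi.ac.uk/ena/browser/api/fasta/CBYO01000001-CBYO01000023"

Without the file the corresponding test fails with a missing-file error;
all other tests are self-contained (fixtures are simulated at run time).
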