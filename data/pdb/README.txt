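Drop asymmetric-unit mmCIF files here (1a73.cif, 1eby.cif, 2ahz.cif) to
enable the accession-anchored acceptance checks, e.g. from
https://files.rcsb.org/download/1A73.cif
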