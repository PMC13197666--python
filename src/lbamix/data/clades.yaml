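# Ten-taxon fixture: abstract leaf names A-J.  Branch lengths in the
# companion Newick files are stand-ins with the canonical structure (two
# long-branched clades separated from everything else by a short internal
# edge); they are NOT estimates from any empirical alignment.
clades:
  AB: [A, B]
  CD: [C, D]
  EF: [E, F]
  GHIJ: [G, H, I, J]
quartet: [AB, CD, EF, GHIJ]
# Stem branches of these two clades are the ones scaled by a BLMF.
long_branch_tags: [AB, EF]
resolutions:
  farris: AB+EF
  felsenstein: AB+CD
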