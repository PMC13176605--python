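"""Tokenize a drug's SMILES and rebuild its molecular graph.

Shows the two molecular views the model consumes: the token sequence (with
special tokens and padding) and the weighted adjacency matrix whose nodes
sit at the atom token positions.
"""

import numpy as np

from pathddi import build_vocab, encode, parse_to_adjacency, tokenize

smiles = "CC(=O)Oc1ccccc1C(=O)O"   # aspirin
tokens = tokenize(smiles)
print(f"SMILES: {smiles}")
print(f"tokens ({len(tokens)}): {tokens}")
print(f"lossless cover: {''.join(tokens) == smiles}")

vocab = build_vocab([smiles])
seq = encode(smiles, vocab, L=32)
print(f"\nencoded IDs (L=32): {seq.ids.tolist()}")
print(f"real-token mask sum: {seq.mask.sum()} "
      "(1 <CLS> + one per kept token)")

graph = parse_to_adjacency(seq.raw_tokens, L=32)
print(f"\natoms: {graph.n_atoms} "
      f"(positions {np.where(graph.atom_mask)[0].tolist()})")
print("bonds (token-position pairs with multiplicity weights;")
print(" 1 = single, 1.5 = aromatic, 2 = double):")
for i, j, w in graph.bonds():
    print(f"  {i:2d} -- {j:2d}  weight {w}")
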