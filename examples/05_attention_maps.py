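"""Export token-level attention maps for inspection.

For a trained model, each decoder layer/head yields a lower-triangular
token-by-token weight matrix: row t shows where the model looks when
predicting the token after position t.
"""

import numpy as np

from graphgpt import SyntheticDatasetSpec, TrainConfig, attention_maps, toy_dataset, train

records = toy_dataset(SyntheticDatasetSpec(n=100, seed=3))
config = TrainConfig(
    epochs=10, batch_size=16, lr=3e-3, seed=1, decoder_layers=2, n_heads=4,
    d_model=64, max_len=64, alignment_dim=8, graph_hidden_dim=8,
)
model = train(records, config).model

maps = attention_maps(model, "Cc1ccccc1")  # toluene, 9 tokens
last_layer = maps.maps[-1].mean(axis=0)  # average over heads
print("tokens:", maps.tokens)
print("last-layer attention (head-averaged, rows = query position):")
with np.printoptions(precision=2, suppress=True):
    print(last_layer)
print("rows sum to 1 over visible positions; zeros above the diagonal are the causal mask")
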