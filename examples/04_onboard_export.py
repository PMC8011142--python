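"""Export a trained model to its compact on-board form and budget deployment.

The compact structure (here: forest node arrays) is everything a
microcontroller needs; the scratch tree-traversal engine reproduces the
training backend's predictions. We also print the storage footprint and
the deployment arithmetic: how strongly on-board classification
compresses the data stream and how many days of behaviour codes fit in
tracker memory.
"""

import ethoclass as ec

config, specs = ec.preset("stork")
bouts = ec.generate_labelled_bouts(specs, 100, config.bout_len_records,
                                   config.fs, seed=2)
table = ec.feature_table(bouts, "simplified", "back")
X = table.drop(columns=["bout_id", "label"])
y = table["label"].to_numpy(dtype=object)

model = ec.train_classifier("rf", X, y,
                            ec.default_hyperparams("rf", "simplified"), seed=0)
compact = ec.export_compact(model)
scratch = ec.predict_compact(compact, X.to_numpy(float))
backend = ec.predict(model, X)
print(f"compact forest: {compact.ntree} trees, "
      f"{sum(len(t) for t in compact.trees)} nodes")
print(f"scratch engine agrees with backend on "
      f"{(scratch == backend).mean() * 100:.1f}% of {len(X)} bouts")

storage = ec.model_storage_bytes(compact, value_bytes=4)
print(f"storage: {storage.total_kb:.3f} kB  {storage.components}")

records = config.bout_len_records
ratio = ec.compression_ratio(records, axes=3, value_bytes=2, label_bytes=1)
days = ec.storage_days(2 ** 20, records / config.fs)
print(f"compression {ratio:.0f}:1 "
      f"({records} records x 3 axes x 2 B vs 1 B behaviour code)")
print(f"1 MiB of memory holds {days} days of behaviour codes")
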