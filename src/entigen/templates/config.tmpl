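scope: model
output: application.cfg
[application]
name = ${name(model)}
entities = ${csv(model.entities, name)}
labels = ${csv(model.entities, label, ", ")}
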