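scope: per_entity
output: mappers/${Name}.sql
-- Data mapper for ${Name(entity)}
-- columns:   ${csv(entity.fields, Name)}
-- dsl types: ${csv(entity.fields, type)}
-- sql types: ${csv(entity.fields, sql_type, "; ")}
SELECT ${csv(entity.fields, Name)} FROM "${Name(entity)}";
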