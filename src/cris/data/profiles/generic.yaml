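# Untagged dialect: bare tokens, double-quoted phrases, '*' truncation.
name: generic
and_token: AND
or_token: OR
wildcard: "*"
phrase_delimiters: ['"', '"']
field_tags: {}
additions: []
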