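# Example dialect modelled on Web-of-Science-style field codes.
name: wos-like
and_token: AND
or_token: OR
wildcard: "*"
phrase_delimiters: ['"', '"']
field_tags:
  title: "TI=({term})"
  abstract: "AB=({term})"
  keywords: "AK=({term})"
max_query_length: 6000
additions: []
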