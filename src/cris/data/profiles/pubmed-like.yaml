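# Example dialect modelled on MEDLINE-style field tags and truncation.
name: pubmed-like
and_token: AND
or_token: OR
wildcard: "*"
phrase_delimiters: ['"', '"']
field_tags:
  title: "{term}[Title]"
  abstract: "{term}[Abstract]"
  keywords: "{term}[Other Term]"
max_query_length: 10000
additions: []
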