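# Per-platform CSS selector configuration for parsing saved comment-section
# HTML snapshots. Selectors follow the simple "tag.class" / ".class" / "tag"
# subset that the fixture generator can also emit.
facebook:
  comment_container_selector: div.comment
  field_selectors:
    name: span.author
    comment: div.comment-text
    likes: span.like-count
    replies: span.reply-count
reddit:
  comment_container_selector: div.reddit-comment
  field_selectors:
    name: a.username
    comment: p.body
    likes: span.upvotes
    replies: span.reply-count
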