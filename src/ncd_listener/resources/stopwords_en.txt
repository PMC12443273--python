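# English stopword list (one token per line, lines starting with # ignored).
# Deliberately keeps personal pronouns, possessives and wh-words, because
# opinion-source and gender cues ("my mother", "what ...") are matched on the
# stopword-removed token stream.
the
a
an
and
or
but
is
are
was
were
be
been
being
am
of
to
in
on
at
for
with
this
that
these
those
have
has
had
do
does
did
not
no
so
very
can
will
would
should
could
as
if
then
than
too
also
just
about
into
over
after
before
up
down
out
again
more
most
some
such
only
own
same
now
all
any
both
each
few
other
nor
once
during
while
because
until
against
between
through
above
below
off
under
further
there
here
from
by
it
its
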