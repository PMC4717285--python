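a
about
after
all
an
and
any
are
as
at
be
been
before
but
by
can
do
does
during
each
for
from
had
has
have
if
in
into
is
it
its
may
most
no
not
of
on
or
other
our
some
such
than
that
the
their
them
then
these
they
this
those
to
was
we
were
which
will
with
you
your
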