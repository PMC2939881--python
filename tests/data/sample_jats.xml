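<?xml version="1.0" encoding="UTF-8"?>
<article article-type="research-article">
  <front>
    <journal-meta>
      <journal-title-group>
        <journal-title>Journal of Synthetic Examples</journal-title>
      </journal-title-group>
    </journal-meta>
    <article-meta>
      <article-id pub-id-type="pmc">PMC0000001</article-id>
      <title-group>
        <article-title>A worked example of structured article parsing</article-title>
      </title-group>
      <contrib-group>
        <contrib contrib-type="author">
          <name><surname>García</surname><given-names>María</given-names></name>
        </contrib>
        <contrib contrib-type="author">
          <name><surname>Smith</surname><given-names>John A.</given-names></name>
        </contrib>
      </contrib-group>
      <pub-date pub-type="ppub"><year>2008</year></pub-date>
      <abstract>
        <p>This abstract describes the study in brief terms for retrieval.</p>
      </abstract>
    </article-meta>
  </front>
  <body>
    <sec>
      <title>Background</title>
      <p>Opening paragraph motivating the study with context.</p>
      <p>Second background paragraph stating the research question.</p>
    </sec>
    <sec>
      <title>Materials and Methods</title>
      <p>Samples were processed following the standard laboratory protocol.</p>
    </sec>
    <sec>
      <title>Results and Discussion</title>
      <p>Observed outcomes are reported and interpreted here.</p>
      <p>Implications and limitations are discussed in closing.</p>
    </sec>
  </body>
</article>
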